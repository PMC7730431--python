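"""Five-layer neuro-fuzzy inference engine (ANFIS-style, Mamdani inference).

The engine mirrors the classic five-layer layout: crisp inputs, triangular
input membership functions, if-then rules (AND = min), clipped output
membership functions aggregated by max, and center-of-gravity (COG)
defuzzification on a fixed discretization of the output domain.

Membership parameters are tuned by finite-difference stochastic gradient
descent, which keeps the trainer simple and exactly checkable against the
forward evaluation it optimizes.  Four instances of this engine drive the
localization pipeline: specular-glare detection, subblock-importance
selection, similarity acceptance, and tracking-source arbitration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangularMF",
    "FuzzyRule",
    "AnfisModel",
    "evaluate",
    "evaluate_batch",
    "train",
    "save_model",
    "load_model",
]

COG_GRID_POINTS = 1001


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``left``/``right`` and apex ``peak``."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right):
            raise ValueError(
                f"triangular MF requires left <= peak <= right, got "
                f"({self.left}, {self.peak}, {self.right})"
            )
        if not np.all(np.isfinite([self.left, self.peak, self.right])):
            raise ValueError("triangular MF parameters must be finite")

    def __call__(self, x):
        """Membership degree in [0, 1]; 0 outside [left, right], 1 at the peak."""
        x = np.asarray(x, dtype=float)
        left, peak, right = self.left, self.peak, self.right
        rising = (x - left) / (peak - left) if peak > left else np.ones_like(x)
        falling = (right - x) / (right - peak) if right > peak else np.ones_like(x)
        out = np.minimum(rising, falling)
        out = np.where((x < left) | (x > right), 0.0, out)
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class FuzzyRule:
    """If-then rule: AND over (input index, MF index) pairs implies one output MF."""

    antecedent: tuple  # tuple of (input_index, mf_index)
    consequent: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"rule weight must lie in [0,1], got {self.weight}")
        object.__setattr__(
            self, "antecedent", tuple((int(i), int(m)) for i, m in self.antecedent)
        )


@dataclass
class AnfisModel:
    """A complete fuzzy system: input partitions, rule base, output partition."""

    n_inputs: int
    input_mfs: list  # per input: list[TriangularMF]
    rules: list  # list[FuzzyRule]
    output_mfs: list  # list[TriangularMF]
    output_domain: tuple = (0.0, 1.0)
    defuzz: str = "cog"
    _grid: np.ndarray = field(default=None, repr=False, compare=False)
    _out_table: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("model needs at least one input")
        if len(self.input_mfs) != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} input MF lists, got {len(self.input_mfs)}"
            )
        for i, mfs in enumerate(self.input_mfs):
            if len(mfs) < 1:
                raise ValueError(f"input {i} has no membership functions")
        if not self.rules:
            raise ValueError("model needs at least one rule")
        if not self.output_mfs:
            raise ValueError("model needs at least one output MF")
        if self.defuzz != "cog":
            raise ValueError(f"unsupported defuzzification method {self.defuzz!r}")
        lo, hi = self.output_domain
        if not hi > lo:
            raise ValueError("output domain must be a nonempty interval")
        for r in self.rules:
            for inp, mf in r.antecedent:
                if not 0 <= inp < self.n_inputs:
                    raise ValueError(f"rule references missing input {inp}")
                if not 0 <= mf < len(self.input_mfs[inp]):
                    raise ValueError(f"rule references missing MF {mf} of input {inp}")
            if not 0 <= r.consequent < len(self.output_mfs):
                raise ValueError(f"rule references missing output MF {r.consequent}")
        self._grid = None
        self._out_table = None

    # -- cached output-grid tabulation ------------------------------------
    def _tables(self):
        if self._grid is None:
            lo, hi = self.output_domain
            self._grid = np.linspace(lo, hi, COG_GRID_POINTS)
            self._out_table = np.stack([mf(self._grid) for mf in self.output_mfs])
        return self._grid, self._out_table

    def __call__(self, x) -> float:
        return evaluate(self, x)

    @classmethod
    def default(
        cls,
        n_inputs: int,
        n_mfs: int,
        input_ranges,
        n_output_mfs: int = None,
        output_domain=(0.0, 1.0),
    ) -> "AnfisModel":
        """Uniformly partition each input with overlapping triangles and wire a
        full rule grid whose consequents interpolate the output partition."""
        n_output_mfs = n_output_mfs or n_mfs
        input_mfs = [
            uniform_partition(lo, hi, n_mfs) for lo, hi in input_ranges
        ]
        output_mfs = uniform_partition(*output_domain, n_output_mfs)
        rules = []
        combos = np.indices([n_mfs] * n_inputs).reshape(n_inputs, -1).T
        for combo in combos:
            frac = np.mean(combo) / max(n_mfs - 1, 1)
            consequent = int(round(frac * (n_output_mfs - 1)))
            rules.append(
                FuzzyRule(tuple((i, int(m)) for i, m in enumerate(combo)), consequent)
            )
        return cls(n_inputs, input_mfs, rules, output_mfs, output_domain)


def uniform_partition(lo: float, hi: float, n: int):
    """n overlapping triangles with peaks uniformly spaced on [lo, hi]."""
    if n == 1:
        return [TriangularMF(lo, 0.5 * (lo + hi), hi)]
    peaks = np.linspace(lo, hi, n)
    step = peaks[1] - peaks[0]
    return [
        TriangularMF(max(lo, p - step) if i else lo, p, min(hi, p + step) if i < n - 1 else hi)
        for i, p in enumerate(peaks)
    ]


def _firing_strengths(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Rule firing strengths, shape (n_samples, n_rules); AND = min."""
    n = X.shape[0]
    W = np.empty((n, len(model.rules)))
    memb = [
        np.stack([mf(X[:, i]) for mf in model.input_mfs[i]])
        for i in range(model.n_inputs)
    ]
    for r, rule in enumerate(model.rules):
        w = np.full(n, rule.weight)
        for inp, mf in rule.antecedent:
            w = np.minimum(w, memb[inp][mf])
        W[:, r] = w
    return W


def evaluate_batch(model: AnfisModel, X) -> np.ndarray:
    """Crisp outputs for a batch of input vectors, shape (n_samples,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected input dimension {model.n_inputs}, got {X.shape[1]}"
        )
    grid, table = model._tables()
    W = _firing_strengths(model, X)  # (n, R)
    cons = np.array([r.consequent for r in model.rules])
    # aggregated output surface: max over rules of min(w_r, mf_cons_r(y))
    clipped = np.minimum(W[:, :, None], table[cons][None, :, :])  # (n, R, G)
    agg = clipped.max(axis=1)  # (n, G)
    area = agg.sum(axis=1)
    lo, hi = model.output_domain
    mid = 0.5 * (lo + hi)
    dead = area <= 0.0
    if np.any(dead):
        warnings.warn(
            "no rule fired for some inputs; returning output-domain midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cog = (agg * grid[None, :]).sum(axis=1) / area
    return np.where(dead, mid, cog)


def evaluate(model: AnfisModel, x) -> float:
    """Crisp output for one input vector via max-min inference and COG."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {x.size}")
    return float(evaluate_batch(model, x[None, :])[0])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _get_params(model: AnfisModel) -> np.ndarray:
    vals = []
    for mfs in model.input_mfs:
        for mf in mfs:
            vals += [mf.left, mf.peak, mf.right]
    for mf in model.output_mfs:
        vals += [mf.left, mf.peak, mf.right]
    return np.array(vals)


def _set_params(model: AnfisModel, params: np.ndarray) -> AnfisModel:
    params = params.copy()
    idx = 0

    def take():
        nonlocal idx
        l, p, r = sorted(params[idx : idx + 3])  # project back to l <= p <= r
        idx += 3
        return TriangularMF(l, p, r)

    input_mfs = [[take() for _ in mfs] for mfs in model.input_mfs]
    output_mfs = [take() for _ in model.output_mfs]
    return AnfisModel(
        model.n_inputs,
        input_mfs,
        list(model.rules),
        output_mfs,
        model.output_domain,
        model.defuzz,
    )


def _project_input_coverage(params: np.ndarray, model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Keep every input's MF partition covering the observed data range.

    Finite-difference gradients plateau once an MF foot crosses past the
    data, so an unconstrained trainer can open dead zones (inputs where no
    rule fires).  After each update the outermost feet are clamped to the
    data range and gaps between consecutive MFs are closed.
    """
    params = params.copy()
    idx = 0
    for i, mfs in enumerate(model.input_mfs):
        k = len(mfs)
        block = np.sort(params[idx : idx + 3 * k].reshape(k, 3), axis=1)
        peaks = block[:, 1]
        order = np.argsort(peaks, kind="stable")
        xmin, xmax = X[:, i].min(), X[:, i].max()
        first, last = order[0], order[-1]
        block[first, 0] = min(block[first, 0], xmin)
        block[last, 2] = max(block[last, 2], xmax)
        for a, b in zip(order[:-1], order[1:]):
            if block[b, 0] > block[a, 2]:  # gap: no membership in between
                mid = 0.5 * (block[b, 0] + block[a, 2])
                block[b, 0] = mid
                block[a, 2] = mid
        block = np.sort(block, axis=1)
        params[idx : idx + 3 * k] = block.ravel()
        idx += 3 * k
    return params


def _rmse(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> float:
    pred = evaluate_batch(model, X)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def train(
    model: AnfisModel,
    samples,
    epochs: int = 50,
    learning_rate: float = 0.05,
    seed: int = 0,
    batch_size: int = 32,
) -> AnfisModel:
    """Tune MF vertices by finite-difference minibatch gradient descent.

    Returns the best model seen during the run, so the training-set RMSE never
    exceeds the initial model's.  Deterministic for a fixed seed.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("training requires at least one sample")
    X = np.array([np.asarray(s[0], dtype=float).ravel() for s in samples])
    y = np.array([float(s[1]) for s in samples])
    if X.shape[1] != model.n_inputs:
        raise ValueError("sample dimension does not match model inputs")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training samples must be finite")

    rng = np.random.default_rng(seed)
    params = _get_params(model)
    scale = max(np.ptp(params), 1.0)
    h = 1e-4 * scale

    best_params = params.copy()
    best_rmse = _rmse(model, X, y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(int(epochs)):
            order = rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                sel = order[start : start + batch_size]
                Xb, yb = X[sel], y[sel]
                grad = np.zeros_like(params)
                for j in range(len(params)):
                    pp = params.copy()
                    pp[j] += h
                    up = _rmse(_set_params(model, pp), Xb, yb)
                    pp[j] -= 2 * h
                    dn = _rmse(_set_params(model, pp), Xb, yb)
                    grad[j] = (up - dn) / (2 * h)
                norm = np.linalg.norm(grad)
                if norm > 0:
                    params = params - learning_rate * scale * grad / norm
                    params = _project_input_coverage(params, model, X)
            cur = _rmse(_set_params(model, params), X, y)
            if cur < best_rmse:
                best_rmse = cur
                best_params = params.copy()

    return _set_params(model, best_params)


# ---------------------------------------------------------------------------
# serialization (JSON, decimal text, exact round-trip)
# ---------------------------------------------------------------------------

def _mf_to_list(mf: TriangularMF):
    return [mf.left, mf.peak, mf.right]


def model_to_dict(model: AnfisModel) -> dict:
    return {
        "n_inputs": model.n_inputs,
        "input_mfs": [[_mf_to_list(m) for m in mfs] for mfs in model.input_mfs],
        "rules": [
            {
                "antecedent": [list(pair) for pair in r.antecedent],
                "consequent": r.consequent,
                "weight": r.weight,
            }
            for r in model.rules
        ],
        "output_mfs": [_mf_to_list(m) for m in model.output_mfs],
        "output_domain": list(model.output_domain),
        "defuzz": model.defuzz,
    }


def model_from_dict(data: dict) -> AnfisModel:
    try:
        input_mfs = [
            [TriangularMF(*map(float, m)) for m in mfs] for mfs in data["input_mfs"]
        ]
        output_mfs = [TriangularMF(*map(float, m)) for m in data["output_mfs"]]
        rules = [
            FuzzyRule(
                tuple((int(i), int(m)) for i, m in r["antecedent"]),
                int(r["consequent"]),
                float(r.get("weight", 1.0)),
            )
            for r in data["rules"]
        ]
        return AnfisModel(
            int(data["n_inputs"]),
            input_mfs,
            rules,
            output_mfs,
            tuple(map(float, data.get("output_domain", (0.0, 1.0)))),
            data.get("defuzz", "cog"),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ValueError(f"malformed ANFIS model file: {exc!r}") from exc


def save_model(model: AnfisModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> AnfisModel:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed ANFIS model file {path}: {exc}") from exc
    return model_from_dict(data)
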