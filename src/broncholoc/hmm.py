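"""Discrete hidden Markov model for junction-sequence path planning.

Airway routes are coded as integer sequences: every bifurcation is a node
and the branches leaving it are numbered, so a route from the trachea to a
target is just the list of fork choices (e.g. 0-0-0 = always take the first
branch).  A discrete HMM mu = (S, O, A, B, pi) trained on previously flown
routes scores candidate codings: the forward algorithm gives sequence
likelihood, Viterbi the most likely hidden-state path, and Baum-Welch (EM)
fits A, B, pi from example sequences, stopping when the mean per-sequence
log-likelihood improves by less than a tolerance (default 0.01).

All recursions run in log space; the default model size is 3 hidden states
over 3 fork symbols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HmmModel",
    "forward_likelihood",
    "forward_log_likelihood",
    "viterbi_path",
    "train_baum_welch",
    "sample_sequences",
    "plan_path",
    "save_hmm",
    "load_hmm",
]

_LOGEPS = -1e30


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log(np.maximum(x, 1e-300)), _LOGEPS)


@dataclass
class HmmModel:
    """mu = (S, O, A, B, pi): row-stochastic transition/emission/initial terms."""

    A: np.ndarray  # (n, n) transitions
    B: np.ndarray  # (n, m) emissions
    pi: np.ndarray  # (n,) initial distribution
    log_history: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        n = self.pi.size
        if self.A.shape != (n, n) or self.B.shape[0] != n:
            raise ValueError("inconsistent HMM dimensions")
        for name, arr in (("A", self.A), ("B", self.B)):
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_obs(self) -> int:
        return self.B.shape[1]

    @classmethod
    def random(cls, n_states: int = 3, n_obs: int = 3, seed: int = 0) -> "HmmModel":
        """Seeded Dirichlet(1) rows; the standard uninformative initialization."""
        rng = np.random.default_rng(seed)
        return cls(
            rng.dirichlet(np.ones(n_states), size=n_states),
            rng.dirichlet(np.ones(n_obs), size=n_states),
            rng.dirichlet(np.ones(n_states)),
        )


def _check_obs(model: HmmModel, obs) -> np.ndarray:
    obs = np.asarray(obs, dtype=int).ravel()
    if obs.size == 0:
        raise ValueError("observation sequence must be non-empty")
    if obs.min() < 0 or obs.max() >= model.n_obs:
        raise ValueError(
            f"observation symbols must lie in [0, {model.n_obs}); got {obs}"
        )
    return obs


def forward_log_likelihood(model: HmmModel, obs) -> float:
    """log P(obs | mu) by the forward recursion in log space."""
    obs = _check_obs(model, obs)
    logA, logB, logpi = _log(model.A), _log(model.B), _log(model.pi)
    alpha = logpi + logB[:, obs[0]]
    for o in obs[1:]:
        alpha = _logsumexp_cols(alpha[:, None] + logA) + logB[:, o]
    return float(_logsumexp(alpha))


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if m <= _LOGEPS:
        return _LOGEPS
    return float(m + np.log(np.exp(v - m).sum()))


def _logsumexp_cols(M: np.ndarray) -> np.ndarray:
    m = M.max(axis=0)
    safe = np.where(m <= _LOGEPS, 0.0, m)
    out = safe + np.log(np.exp(M - safe[None, :]).sum(axis=0))
    return np.where(m <= _LOGEPS, _LOGEPS, out)


def forward_likelihood(model: HmmModel, obs) -> float:
    """P(obs | mu) in (0, 1]."""
    return float(np.exp(forward_log_likelihood(model, obs)))


def viterbi_path(model: HmmModel, obs):
    """Most likely hidden-state sequence and its joint log probability.

    Ties break toward the lower state index (argmax returns the first max).
    """
    obs = _check_obs(model, obs)
    logA, logB, logpi = _log(model.A), _log(model.B), _log(model.pi)
    T, n = obs.size, model.n_states
    delta = logpi + logB[:, obs[0]]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA  # (from, to)
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logB[:, obs[t]]
    states = np.zeros(T, dtype=int)
    states[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states.tolist(), float(delta.max())


# ---------------------------------------------------------------------------
# Baum-Welch training
# ---------------------------------------------------------------------------

def _forward_backward_scaled(model: HmmModel, obs: np.ndarray):
    """Scaled forward/backward passes; returns (alpha, beta, scales, loglik)."""
    A, B, pi = model.A, model.B, model.pi
    T, n = obs.size, model.n_states
    alpha = np.zeros((T, n))
    scales = np.zeros(T)
    alpha[0] = pi * B[:, obs[0]]
    scales[0] = alpha[0].sum() or 1e-300
    alpha[0] /= scales[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[:, obs[t]]
        scales[t] = alpha[t].sum() or 1e-300
        alpha[t] /= scales[t]
    beta = np.zeros((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A * B[:, obs[t + 1]][None, :]) @ beta[t + 1]
        beta[t] /= scales[t + 1]
    return alpha, beta, scales, float(np.log(scales).sum())


def train_baum_welch(
    sequences,
    n_states: int = 3,
    n_obs: int = None,
    seed: int = 0,
    tol: float = 0.01,
    max_iters: int = 200,
    n_restarts: int = 5,
) -> HmmModel:
    """EM estimation of (A, B, pi) from fork-label sequences.

    Convergence: stop once the change in mean per-sequence log-likelihood
    drops below ``tol``.  EM only finds local optima, so ``n_restarts``
    seeded initializations are run and the fit with the best training
    log-likelihood kept.  The fitted model records that run's per-iteration
    mean log-likelihood in ``log_history`` (non-decreasing, by EM
    monotonicity).  Deterministic for a fixed seed.
    """
    seqs = [np.asarray(s, dtype=int).ravel() for s in sequences]
    if not seqs:
        raise ValueError("training requires at least one sequence")
    if any(s.size == 0 for s in seqs):
        raise ValueError("training sequences must be non-empty")
    if n_obs is None:
        n_obs = int(max(s.max() for s in seqs)) + 1
    if any(s.min() < 0 or s.max() >= n_obs for s in seqs):
        raise ValueError("sequence symbols out of range")
    best = None
    for r in range(max(int(n_restarts), 1)):
        model = _baum_welch_single(seqs, n_states, n_obs, seed + r, tol, max_iters)
        if best is None or model.log_history[-1] > best.log_history[-1]:
            best = model
    return best


def _baum_welch_single(seqs, n_states, n_obs, seed, tol, max_iters) -> HmmModel:
    model = HmmModel.random(n_states, n_obs, seed)
    history = []
    prev_mean = None
    for _ in range(int(max_iters)):
        A_num = np.zeros((n_states, n_states))
        B_num = np.zeros((n_states, n_obs))
        pi_num = np.zeros(n_states)
        gamma_sum = np.zeros(n_states)
        gamma_sum_nolast = np.zeros(n_states)
        total_ll = 0.0
        for obs in seqs:
            alpha, beta, scales, ll = _forward_backward_scaled(model, obs)
            total_ll += ll
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
            pi_num += gamma[0]
            for k in range(n_obs):
                B_num[:, k] += gamma[obs == k].sum(axis=0)
            gamma_sum += gamma.sum(axis=0)
            gamma_sum_nolast += gamma[:-1].sum(axis=0)
            for t in range(obs.size - 1):
                xi = (
                    alpha[t][:, None]
                    * model.A
                    * model.B[:, obs[t + 1]][None, :]
                    * beta[t + 1][None, :]
                ) / scales[t + 1]
                xi /= max(xi.sum(), 1e-300)
                A_num += xi
        mean_ll = total_ll / len(seqs)
        history.append(mean_ll)
        if prev_mean is not None and abs(mean_ll - prev_mean) < tol:
            break
        prev_mean = mean_ll
        A_new = A_num / np.maximum(gamma_sum_nolast[:, None], 1e-300)
        B_new = B_num / np.maximum(gamma_sum[:, None], 1e-300)
        pi_new = pi_num / len(seqs)
        # guard rows that received no mass (unvisited states)
        A_new = np.where(A_new.sum(axis=1, keepdims=True) > 0, A_new, 1.0 / n_states)
        B_new = np.where(B_new.sum(axis=1, keepdims=True) > 0, B_new, 1.0 / n_obs)
        A_new /= A_new.sum(axis=1, keepdims=True)
        B_new /= B_new.sum(axis=1, keepdims=True)
        pi_new = np.maximum(pi_new, 0.0)
        pi_new /= pi_new.sum()
        model = HmmModel(A_new, B_new, pi_new)
    model.log_history = history
    return model


def sample_sequences(model: HmmModel, n: int, length: int, seed: int = 0):
    """Draw n observation sequences of the given length from the model."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        s = rng.choice(model.n_states, p=model.pi)
        obs = []
        for _ in range(length):
            obs.append(int(rng.choice(model.n_obs, p=model.B[s])))
            s = rng.choice(model.n_states, p=model.A[s])
        out.append(obs)
    return out


# ---------------------------------------------------------------------------
# path planning over the airway junction graph
# ---------------------------------------------------------------------------

def _fork_code_for_path(airway, nodes):
    """Branch labels chosen at each node along a path.

    Every traversed node contributes one symbol — the index of the chosen
    branch among that node's children ordered by label — so a straight
    run down first branches in a 3-generation tree reads 0-0-0.
    """
    code = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        children = airway.children_of(a)
        code.append(children.index(b))
    return code


def plan_path(model: HmmModel, airway, source: str, target: str):
    """Most likely fork coding from source to target junction.

    Enumerates the simple directed paths between the junctions (unique in a
    tree), codes each as its fork-label sequence, and returns the coding
    with maximal forward likelihood together with the concatenated
    centerline polyline for display.  Returns (code, node_path, polyline,
    log_likelihood); an empty code for source == target.
    """
    import networkx as nx

    g = airway.graph
    for n in (source, target):
        if n not in g:
            raise KeyError(f"junction {n!r} not in airway graph")
    if source == target:
        return [], [source], np.zeros((0, 3)), 0.0
    paths = list(nx.all_simple_paths(g, source, target))
    if not paths:
        raise ValueError(f"junction {target!r} is unreachable from {source!r}")
    best = None
    for nodes in paths:
        code = _fork_code_for_path(airway, nodes)
        ll = forward_log_likelihood(model, code) if code else 0.0
        if best is None or ll > best[3]:
            best = (code, nodes, None, ll)
    code, nodes, _, ll = best
    pts = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        poly = np.asarray(g.edges[a, b]["polyline"], dtype=float)
        pts.append(poly if not pts else poly[1:])
    polyline = np.vstack(pts) if pts else np.zeros((0, 3))
    return code, nodes, polyline, ll


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_hmm(model: HmmModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_states": model.n_states,
                "n_obs": model.n_obs,
                "A": model.A.tolist(),
                "B": model.B.tolist(),
                "pi": model.pi.tolist(),
            },
            fh,
            indent=1,
        )


def load_hmm(path) -> HmmModel:
    with open(path) as fh:
        data = json.load(fh)
    return HmmModel(np.array(data["A"]), np.array(data["B"]), np.array(data["pi"]))


def load_sequences(path):
    """Training sequences: one whitespace-separated label sequence per line."""
    seqs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                seqs.append([int(tok) for tok in line.split()])
    return seqs
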