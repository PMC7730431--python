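"""Shipped default fuzzy decision models for the four pipeline decision points.

The models are constructed in code (deterministically, no stored artifacts)
as small hand-set triangular rule bases encoding the qualitative logic each
decision needs:

* glare:       high value AND low saturation  -> glare
* importance:  large non-uniformity statistic -> informative block
* similarity:  high normalized shape-context similarity -> accept pose
* arbitration: sudden motion OR weak feature confidence -> trust optical flow

All outputs live on [0, 1] and the pipeline thresholds them at 0.5.  Any of
these can be replaced by a model trained with :func:`broncholoc.anfis.train`
or loaded from JSON.
"""

from __future__ import annotations

from .anfis import AnfisModel, FuzzyRule, TriangularMF

__all__ = [
    "default_glare_model",
    "default_importance_model",
    "default_similarity_model",
    "default_arbitration_model",
]

_OUT_NO = TriangularMF(0.0, 0.0, 0.5)
_OUT_YES = TriangularMF(0.5, 1.0, 1.0)


def default_glare_model() -> AnfisModel:
    """Inputs: (mean saturation, mean value), both in [0, 1].

    Specular glare saturates the sensor: value near 1, saturation near 0.
    Tissue keeps its color ratio regardless of shading (saturation ~0.4),
    so low mean saturation is the primary glare signature and mean value
    gates out dark regions; the crossover sits where roughly half of a
    block's pixels are saturated white.
    """
    s_low = TriangularMF(0.0, 0.0, 0.42)
    s_high = TriangularMF(0.0, 0.42, 1.0)
    v_low = TriangularMF(0.0, 0.0, 0.35)
    v_high = TriangularMF(0.25, 1.0, 1.0)
    rules = [
        FuzzyRule(((0, 0), (1, 1)), 1),  # S low  & V high -> glare
        FuzzyRule(((0, 1),), 0),         # S high          -> clean
        FuzzyRule(((1, 0),), 0),         # V low           -> clean
    ]
    return AnfisModel(2, [[s_low, s_high], [v_low, v_high]], rules, [_OUT_NO, _OUT_YES])


def default_importance_model(block_pixels: int = 1600) -> AnfisModel:
    """Single input: the non-uniformity statistic I = N * SD^2 of a block.

    The uniform/non-uniform crossover is placed at an intensity SD of about
    1% of full scale (I = N * 1e-4 for an N-pixel block); blocks of other
    sizes can pass their pixel count to keep the crossover at the same SD.
    """
    i_cross = block_pixels * 0.01**2
    i_low = TriangularMF(0.0, 0.0, 2.0 * i_cross)
    i_high = TriangularMF(0.0, 2.0 * i_cross, 0.25 * float(block_pixels))
    rules = [FuzzyRule(((0, 0),), 0), FuzzyRule(((0, 1),), 1)]
    return AnfisModel(
        1, [[i_low, i_high]], rules, [_OUT_NO, _OUT_YES], output_domain=(0.0, 1.0)
    )


def default_similarity_model() -> AnfisModel:
    """Single input: normalized shape-context similarity s in [0, 1].

    The acceptance crossover sits near s = 0.985: with count histograms
    over ~100-200 salient blocks, a correctly registered pair scores above
    0.99 while a pose off by a couple of millimetres typically scores
    0.94-0.98, so the discriminating band is narrow and high.
    """
    s_low = TriangularMF(0.0, 0.0, 0.995)
    s_high = TriangularMF(0.985, 1.0, 1.0)
    rules = [FuzzyRule(((0, 0),), 0), FuzzyRule(((0, 1),), 1)]
    return AnfisModel(1, [[s_low, s_high]], rules, [_OUT_NO, _OUT_YES])


def default_arbitration_model() -> AnfisModel:
    """Inputs: (motion suddenness, feature-match confidence).

    Suddenness is the deviation of the candidate feature-based displacement
    from recent history, in units of the mean historic step (clipped to
    [0, 10] before evaluation).  Output >= 0.5 means: distrust the feature
    vector, wait for optical flow.
    """
    sud_low = TriangularMF(0.0, 0.0, 3.0)
    sud_high = TriangularMF(1.8, 10.0, 10.0)
    conf_low = TriangularMF(0.0, 0.0, 0.45)
    conf_high = TriangularMF(0.25, 1.0, 1.0)
    rules = [
        FuzzyRule(((0, 1),), 1),          # sudden            -> flow
        FuzzyRule(((1, 0),), 1),          # weak confidence   -> flow
        FuzzyRule(((0, 0), (1, 1)), 0),   # calm & confident  -> features
    ]
    return AnfisModel(
        2, [[sud_low, sud_high], [conf_low, conf_high]], rules, [_OUT_NO, _OUT_YES]
    )
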