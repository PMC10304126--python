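"""WAASB stability index, quadrant classification and the WAASBY blend.

WAASB is the weighted average of a genotype's (or environment's) absolute
IPCA scores from the singular value decomposition of the BLUP-shrunken GE
matrix, each axis weighted by the share of interaction variance it
explains:

    WAASB_i = sum_k |IPCA_ik| EP_k / sum_k EP_k,   k = 1..p.

All p = min(g-1, e-1) axes enter.  A WAASB of zero means the entity sits
on no interaction axis at all — maximal stability (for a genotype) or no
discriminative ability (for an environment).

The WAASB-by-yield plane is cut into four quadrants at the means of the
plotted yields and WAASB values: I = low yield / high WAASB, II = high
yield / high WAASB, III = low yield / low WAASB, IV = high yield / low
WAASB.  Quadrant IV genotypes are productive with broad adaptability;
for environments the reading flips (quadrant II environments are
productive and discriminating).  Ties sit on the favourable side: yield
at the cut-off counts as high, WAASB at the cut-off counts as stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ammi import fit_ammi
from .blup import fit_blup
from .data import METDataError, METDataset, cell_means

__all__ = [
    "StabilityResult",
    "waasb",
    "quadrant_classify",
    "waasby",
    "stability_analysis",
]


@dataclass
class StabilityResult:
    """WAASB, mean yield and quadrant for genotypes and environments."""

    genotypes: pd.DataFrame     # index genotype; yield, WAASB, quadrant
    environments: pd.DataFrame  # index environment; yield, WAASB, quadrant

    def table(self) -> pd.DataFrame:
        """Single tidy table: entity, type, yield, WAASB, quadrant."""
        a = self.genotypes.reset_index(names="entity")
        a.insert(1, "type", "GEN")
        b = self.environments.reset_index(names="entity")
        b.insert(1, "type", "ENV")
        return pd.concat([a, b], ignore_index=True)


def waasb(scores: pd.DataFrame | np.ndarray, ep) -> pd.Series:
    """Weighted average of absolute IPCA scores.

    ``scores`` is entity x axis; ``ep`` the per-axis variance-explained
    weights (non-negative).  With every weight zero — a zero interaction
    matrix — every entity scores 0.
    """
    s = pd.DataFrame(scores)
    w = np.asarray(ep, dtype=float)
    if w.ndim != 1 or len(w) != s.shape[1]:
        raise METDataError(
            f"need one weight per axis: {s.shape[1]} axes, {len(w)} weights")
    if (w < 0).any():
        raise METDataError("variance-explained weights must be >= 0")
    tot = w.sum()
    if tot == 0:
        return pd.Series(0.0, index=s.index)
    return (s.abs() * w).sum(axis=1) / tot


def quadrant_classify(yields: pd.Series, waasb_values: pd.Series,
                      yield_cutoff: float | None = None,
                      waasb_cutoff: float | None = None) -> pd.Series:
    """Assign quadrant labels I-IV from yield and WAASB.

    Cut-offs default to the means of the supplied vectors.  ``yield >=
    cut-off`` counts as high-yielding and ``WAASB <= cut-off`` as stable,
    so an entity sitting exactly on both crosshairs lands in quadrant IV.
    """
    y = pd.Series(yields, dtype=float)
    w = pd.Series(waasb_values, dtype=float)
    if not y.index.equals(w.index):
        w = w.reindex(y.index)
        if w.isna().any():
            raise METDataError("yield and WAASB vectors are not aligned")
    if len(y) < 2:
        raise METDataError("quadrant classification needs >= 2 entities")
    yc = float(y.mean()) if yield_cutoff is None else float(yield_cutoff)
    wc = float(w.mean()) if waasb_cutoff is None else float(waasb_cutoff)
    high = y >= yc
    stable = w <= wc
    out = pd.Series("I", index=y.index, name="quadrant")
    out[high & ~stable] = "II"
    out[~high & stable] = "III"
    out[high & stable] = "IV"
    return out


def waasby(yields: pd.Series, waasb_values: pd.Series,
           weight_y: float = 50.0) -> pd.Series:
    """Blend of rescaled mean performance and stability, in [0, 100].

    Yields are rescaled linearly so the best genotype scores 100; WAASB is
    rescaled inversely so the most stable genotype scores 100.  The blend
    is (weight_y * Y' + (100 - weight_y) * W') / 100.
    """
    if not 0.0 <= weight_y <= 100.0:
        raise METDataError(f"weight_y must be in [0, 100], got {weight_y}")
    y = pd.Series(yields, dtype=float)
    w = pd.Series(waasb_values, dtype=float).reindex(y.index)
    if y.max() == y.min() or w.max() == w.min():
        raise METDataError("cannot rescale a constant yield or WAASB vector")
    y_r = 100.0 * (y - y.min()) / (y.max() - y.min())
    w_r = 100.0 * (w.max() - w) / (w.max() - w.min())
    return (weight_y * y_r + (100.0 - weight_y) * w_r) / 100.0


def stability_analysis(data: METDataset,
                       scaling: str = "symmetric") -> StabilityResult:
    """Full WAASB pipeline on a balanced dataset.

    Estimates variance components, forms the BLUP-shrunken GE matrix,
    decomposes it, scores both sides (sqrt-singular-value symmetric
    scaling by default, so genotypes and environments share one biplot),
    and classifies each side into quadrants against its own mean cut-offs.
    """
    bf = fit_blup(data)
    # the BLUP GE matrix is already doubly centered, so the re-centering
    # inside fit_ammi is a no-op and the SVD applies to the matrix itself
    fit = fit_ammi(bf.ge_matrix, r=data.r, residual_ms=0.0)
    tab = cell_means(data)
    gen_scores = fit.scores("genotype", scaling=scaling)
    env_scores = fit.scores("environment", scaling=scaling)
    gen_w = waasb(gen_scores, fit.explained)
    env_w = waasb(env_scores, fit.explained)
    gen_y = tab.mean(axis=1)
    env_y = tab.mean(axis=0)
    gen = pd.DataFrame({"yield": gen_y, "WAASB": gen_w,
                        "quadrant": quadrant_classify(gen_y, gen_w)})
    env = pd.DataFrame({"yield": env_y, "WAASB": env_w,
                        "quadrant": quadrant_classify(env_y, env_w)})
    return StabilityResult(genotypes=gen, environments=env)
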