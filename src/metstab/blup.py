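"""BLUP of genotype means and the shrunken GE matrix.

Model: genotype effects and genotype-by-environment interaction are
random; environments and blocks are fixed and enter only through the
centering.  On balanced data the ANOVA (method-of-moments) estimators
from expected mean squares are

    sigma2_res = MS_res
    sigma2_ge  = max(0, (MS_GE - MS_res) / r)
    sigma2_g   = max(0, (MS_G - MS_GE) / (e * r))

and coincide with REML away from the truncation boundaries.  The best
linear unbiased predictor of a genotype mean shrinks its raw mean toward
the grand mean,

    BLUP_g = mu + w (ybar_g. - mu),
    w = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_res / (e r)),

and the BLUP GE matrix shrinks each doubly-centered interaction residual
by s = sigma2_ge / (sigma2_ge + sigma2_res / r).  That shrunken matrix is
the input to the WAASB stability index.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .data import METDataset, cell_means
from .ammi import AnovaTable, joint_anova

__all__ = [
    "VarianceComponents",
    "BLUPFit",
    "variance_components",
    "genotype_blups",
    "blup_ge_matrix",
    "fit_blup",
]


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA-based variance components of the balanced two-way MET model."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_res: float
    method: str = "anova"

    def shrinkage_weight(self, e: int, r: int) -> float:
        """Weight w applied to a genotype's raw mean deviation."""
        denom = (self.sigma2_g + self.sigma2_ge / e
                 + self.sigma2_res / (e * r))
        return self.sigma2_g / denom if denom > 0 else 0.0

    def ge_shrinkage(self, r: int) -> float:
        """Weight s applied to each interaction residual."""
        denom = self.sigma2_ge + self.sigma2_res / r
        return self.sigma2_ge / denom if denom > 0 else 0.0


@dataclass
class BLUPFit:
    """Variance components plus shrunken genotype means and GE matrix."""

    vc: VarianceComponents
    grand_mean: float
    genotype_means: pd.Series   # mu + shrunken effect, original label order
    ge_matrix: pd.DataFrame     # g x e, doubly centered

    def ranking(self) -> pd.Series:
        """Predicted genotype means, best first."""
        return self.genotype_means.sort_values(ascending=False)


def variance_components(data: METDataset,
                        anova: AnovaTable | None = None) -> VarianceComponents:
    """Moment estimators of sigma2_g, sigma2_ge, sigma2_res.

    Negative solutions of the expected-mean-square equations are truncated
    at zero (with a warning) before any shrinkage weight is formed.
    """
    an = anova if anova is not None else joint_anova(data)
    ms_g = float(an.table.loc["GEN", "MS"])
    ms_ge = float(an.table.loc["GEN:ENV", "MS"])
    ms_res = an.residual_ms
    raw_ge = (ms_ge - ms_res) / an.r
    raw_g = (ms_g - ms_ge) / (an.e * an.r)
    if raw_ge < 0 or raw_g < 0:
        warn("negative variance-component estimate truncated at zero",
             stacklevel=2)
    return VarianceComponents(
        sigma2_g=max(raw_g, 0.0),
        sigma2_ge=max(raw_ge, 0.0),
        sigma2_res=ms_res,
    )


def genotype_blups(data: METDataset,
                   vc: VarianceComponents | None = None) -> pd.Series:
    """Shrunken genotype means mu + w (ybar_g. - mu).

    With sigma2_g = 0 every prediction equals the grand mean; with no
    non-genetic variance w = 1 and the raw means are returned unchanged.
    """
    data.require_balanced("genotype BLUPs")
    if vc is None:
        vc = variance_components(data)
    tab = cell_means(data)
    mu = float(tab.to_numpy().mean())
    w = vc.shrinkage_weight(e=tab.shape[1], r=data.r)
    return mu + w * (tab.mean(axis=1) - mu)


def blup_ge_matrix(data: METDataset,
                   vc: VarianceComponents | None = None) -> pd.DataFrame:
    """Shrunken doubly-centered interaction matrix s * Z.

    Z_ge = ybar_ge - ybar_g. - ybar_.e + ybar.. ; s in [0, 1].  A zero
    sigma2_ge gives the zero matrix (WAASB then degenerates to 0 for every
    genotype and environment).
    """
    data.require_balanced("the BLUP GE matrix")
    if vc is None:
        vc = variance_components(data)
    tab = cell_means(data)
    y = tab.to_numpy()
    z = (y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
         + y.mean())
    s = vc.ge_shrinkage(r=data.r)
    return pd.DataFrame(s * z, index=tab.index, columns=tab.columns)


def fit_blup(data: METDataset) -> BLUPFit:
    """Variance components, genotype BLUPs and GE matrix in one pass."""
    an = joint_anova(data)
    vc = variance_components(data, anova=an)
    preds = genotype_blups(data, vc)
    ge = blup_ge_matrix(data, vc)
    return BLUPFit(vc=vc, grand_mean=float(cell_means(data).to_numpy().mean()),
                   genotype_means=preds, ge_matrix=ge)
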