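"""Per-environment descriptives, broad-sense heritability and class summaries.

Within one environment the trial is a randomized complete block design
(RCBD): every genotype appears once in each of r blocks.  The two-way
genotype x block ANOVA of that trial yields the residual mean square used
for the trial CV, and the genotype mean square used for the plot-basis
broad-sense heritability

    H^2 = sigma2_g / (sigma2_g + sigma2_res),
    sigma2_g = max(0, (MS_G - MS_res) / r).

Negative moment estimates are truncated at zero, so H^2 lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DegeneracyError, METDataError, METDataset

__all__ = [
    "EnvSummary",
    "rcbd_anova",
    "env_summary",
    "heritability",
    "heritability_bins",
    "yield_reduction",
    "common_env_class_means",
    "summarize_environments",
]


@dataclass(frozen=True)
class EnvSummary:
    """Descriptives of one environment's trial."""

    environment: str
    mean: float          # t/ha over all plots
    cv: float | None     # %, residual-based; None if not estimable
    heritability: float | None  # plot-basis H^2 in [0,1]


def rcbd_anova(sub: pd.DataFrame) -> dict[str, float]:
    """Genotype x block ANOVA of one environment's plots.

    Expects a tidy frame with columns genotype, replicate, yield covering a
    complete g x r layout.  Returns mean squares and degrees of freedom.
    """
    piv = sub.pivot_table(index="genotype", columns="replicate",
                          values="yield", aggfunc="mean")
    if piv.isna().any().any():
        raise METDataError("environment is not a complete genotype x block "
                           "layout")
    y = piv.to_numpy()
    g, r = y.shape
    if g < 2 or r < 2:
        raise METDataError(f"need >=2 genotypes and >=2 blocks, got "
                           f"g={g}, r={r}")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_gen = r * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_block = g * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_res = ss_total - ss_gen - ss_block
    df_gen, df_block = g - 1, r - 1
    df_res = (g - 1) * (r - 1)
    return {
        "g": g, "r": r, "grand_mean": grand,
        "ss_gen": ss_gen, "ss_block": ss_block, "ss_res": max(ss_res, 0.0),
        "df_gen": df_gen, "df_block": df_block, "df_res": df_res,
        "ms_gen": ss_gen / df_gen,
        "ms_res": max(ss_res, 0.0) / df_res,
    }


def env_summary(data: METDataset, environment: str) -> EnvSummary:
    """Mean, residual-based CV and heritability for one environment.

    CV = 100 * sqrt(MS_res) / mean, with MS_res from the within-environment
    RCBD ANOVA (genotype and block effects removed), the convention for
    trial-quality CVs in breeding reports.
    """
    sub = data.environment_subset(environment)
    mean = float(sub["yield"].mean())
    try:
        an = rcbd_anova(sub)
    except METDataError:
        return EnvSummary(environment, mean, None, None)
    cv = 100.0 * float(np.sqrt(an["ms_res"])) / mean if mean != 0 else None
    try:
        h2 = heritability(data, environment)
    except DegeneracyError:
        h2 = None
    return EnvSummary(environment, mean, cv, h2)


def heritability(data: METDataset, environment: str) -> float:
    """Plot-basis broad-sense heritability of one environment's trial."""
    an = rcbd_anova(data.environment_subset(environment))
    sigma2_res = an["ms_res"]
    sigma2_g = max(0.0, (an["ms_gen"] - an["ms_res"]) / an["r"])
    total = sigma2_g + sigma2_res
    if total <= 0:
        raise DegeneracyError(
            f"no variation in environment {environment!r}")
    return float(np.clip(sigma2_g / total, 0.0, 1.0))


def heritability_bins(values) -> dict[str, float]:
    """Proportions of H^2 values in the bins >=0.5, [0.2, 0.5) and <0.2."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise METDataError("empty heritability list")
    n = v.size
    high = float((v >= 0.5).sum()) / n
    mid = float(((v >= 0.2) & (v < 0.5)).sum()) / n
    low = float((v < 0.2).sum()) / n
    return {"high": high, "mid": mid, "low": low}


def yield_reduction(env_means) -> float:
    """Percent yield drop from the best to the worst environment.

    100 * (max - min) / max over the per-environment means of one market
    class; NaN entries (class absent from an environment) are ignored.
    """
    v = np.asarray(pd.Series(env_means).dropna(), dtype=float)
    if v.size < 2:
        raise METDataError("need means for at least two environments")
    hi, lo = float(v.max()), float(v.min())
    if hi == 0:
        raise METDataError("maximum environment mean is zero")
    return 100.0 * (hi - lo) / hi


def common_env_class_means(table: pd.DataFrame) -> pd.Series:
    """Per-class mean yield over environments shared by every class.

    ``table`` is environment x class; rows with any missing class are
    dropped before averaging, so classes are compared on identical
    environment sets.
    """
    shared = table.dropna(axis=0, how="any")
    if shared.empty:
        raise METDataError("no environment has a value for every class")
    return shared.mean(axis=0)


def summarize_environments(data: METDataset) -> pd.DataFrame:
    """Tidy ENV / MEAN / CV / H2 table over all environments."""
    rows = []
    for env in data.environments:
        s = env_summary(data, env)
        rows.append((s.environment, s.mean, s.cv, s.heritability))
    return pd.DataFrame(rows, columns=["ENV", "MEAN", "CV", "H2"])
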