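"""AMMI: additive main effects and multiplicative interaction.

The joint fixed-effects ANOVA of a balanced MET partitions plot-level
variation into environments, blocks within environments, genotypes, the
genotype-by-environment interaction (GE) and residual.  AMMI then
decomposes the doubly-centered matrix of cell means

    Z_ge = ybar_ge - ybar_g. - ybar_.e + ybar..

by singular value decomposition; the k-th multiplicative axis (IPCA_k)
carries a share EP_k = lambda_k^2 / sum(lambda^2) of the interaction sum
of squares.  AMMIk retains the first k axes; AMMI0 is the additive model
and AMMIF the full decomposition, which reproduces the cell means exactly.

Axis F-tests use Gollob degrees of freedom df_k = g + e - 1 - 2k against
the pooled RCBD residual, with axis sums of squares converted to the plot
basis (r * lambda_k^2).  The GE sum of squares splits into a noise part,
df_GE * MS_res — the amount a pure-error interaction of those degrees of
freedom would show — and the remainder, treated as real interaction signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import BalanceError, METDataError, METDataset, cell_means

__all__ = [
    "AnovaTable",
    "AMMIFit",
    "GEPartition",
    "joint_anova",
    "fit_ammi",
    "ipca_tests",
    "ge_signal_noise",
    "predict_ammi",
]


@dataclass(frozen=True)
class AnovaTable:
    """Joint MET ANOVA with G/E/GE shares of the non-residual variation."""

    table: pd.DataFrame          # index: source; df, SS, MS, F, p
    shares: dict[str, float]     # G, E, GE fractions of SS_G+SS_E+SS_GE
    g: int
    e: int
    r: int

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "MS"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])


@dataclass
class AMMIFit:
    """Additive effects plus SVD of the centered interaction matrix."""

    grand_mean: float
    genotype_effects: pd.Series     # alpha_g, sums to 0
    environment_effects: pd.Series  # beta_e, sums to 0
    singular_values: np.ndarray     # lambda_k, nonincreasing, length p
    genotype_vectors: pd.DataFrame  # gamma, g x p, orthonormal columns
    environment_vectors: pd.DataFrame  # delta, e x p, orthonormal columns
    explained: np.ndarray           # EP_k, sums to 1 (or all 0 if rank 0)
    r: int
    residual_ms: float
    residual_df: int | None = None
    anova: AnovaTable | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.singular_values)

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_effects.index)

    @property
    def environments(self) -> list[str]:
        return list(self.environment_effects.index)

    def scores(self, side: str = "genotype",
               scaling: str = "symmetric") -> pd.DataFrame:
        """IPCA scores, axes as columns ``IPCA1..IPCAp``.

        ``symmetric`` scales both sides by sqrt(lambda) so genotypes and
        environments share one biplot; ``genotype`` puts the full singular
        values on the genotype side, ``environment`` on the environment side.
        """
        if side == "genotype":
            vec = self.genotype_vectors.to_numpy()
        elif side == "environment":
            vec = self.environment_vectors.to_numpy()
        else:
            raise ValueError(f"side must be genotype/environment, got {side!r}")
        lam = self.singular_values
        if scaling == "symmetric":
            fac = np.sqrt(lam)
        elif scaling == side:
            fac = lam
        elif scaling in ("genotype", "environment"):
            fac = np.ones_like(lam)
        else:
            raise ValueError(f"unknown scaling {scaling!r}")
        idx = (self.genotypes if side == "genotype" else self.environments)
        return pd.DataFrame(vec * fac, index=idx,
                            columns=[f"IPCA{k + 1}" for k in range(self.p)])


@dataclass(frozen=True)
class GEPartition:
    """Signal/noise split of the interaction sum of squares (plot basis)."""

    ss_ge: float
    noise: float
    signal: float
    signal_fraction: float


def joint_anova(data: METDataset) -> AnovaTable:
    """Fixed-effects ANOVA of a balanced MET.

    Sources: ENV (df e-1), REP(ENV) (df e(r-1)), GEN (df g-1), GEN:ENV
    (df (g-1)(e-1)) and Residual (df e(g-1)(r-1)).  GEN and GEN:ENV are
    tested against the residual; ENV against REP(ENV).  ``shares`` gives
    each of G, E and GE as a fraction of SS_G + SS_E + SS_GE.
    """
    data.require_balanced("the joint ANOVA")
    y = data.to_array()
    g, e, r = y.shape
    if g < 2 or e < 2 or r < 2:
        raise METDataError(f"need g, e, r >= 2; got g={g}, e={e}, r={r}")
    grand = y.mean()
    env_m = y.mean(axis=(0, 2))
    gen_m = y.mean(axis=(1, 2))
    rep_m = y.mean(axis=0)              # e x r block means
    cell = y.mean(axis=2)

    ss_total = float(((y - grand) ** 2).sum())
    ss_env = float(g * r * ((env_m - grand) ** 2).sum())
    ss_rep = float(g * ((rep_m - env_m[:, None]) ** 2).sum())
    ss_gen = float(e * r * ((gen_m - grand) ** 2).sum())
    z = cell - gen_m[:, None] - env_m[None, :] + grand
    ss_ge = float(r * (z ** 2).sum())
    ss_res = max(ss_total - ss_env - ss_rep - ss_gen - ss_ge, 0.0)

    rows = {
        "ENV": (e - 1, ss_env),
        "REP(ENV)": (e * (r - 1), ss_rep),
        "GEN": (g - 1, ss_gen),
        "GEN:ENV": ((g - 1) * (e - 1), ss_ge),
        "Residual": (e * (g - 1) * (r - 1), ss_res),
    }
    tab = pd.DataFrame(
        {"df": {k: v[0] for k, v in rows.items()},
         "SS": {k: v[1] for k, v in rows.items()}})
    tab["MS"] = tab["SS"] / tab["df"]
    ms_res = tab.loc["Residual", "MS"]
    ms_rep = tab.loc["REP(ENV)", "MS"]
    f_col, p_col = {}, {}
    for src, denom, ddf in (("ENV", ms_rep, rows["REP(ENV)"][0]),
                            ("GEN", ms_res, rows["Residual"][0]),
                            ("GEN:ENV", ms_res, rows["Residual"][0])):
        if denom > 0:
            f = tab.loc[src, "MS"] / denom
            f_col[src] = f
            p_col[src] = float(stats.f.sf(f, tab.loc[src, "df"], ddf))
        else:
            f_col[src] = np.inf if tab.loc[src, "MS"] > 0 else 0.0
            p_col[src] = 0.0 if tab.loc[src, "MS"] > 0 else 1.0
    tab["F"] = pd.Series(f_col)
    tab["p"] = pd.Series(p_col)
    tab.loc["Total"] = [g * e * r - 1, ss_total, np.nan, np.nan, np.nan]

    geg = ss_gen + ss_env + ss_ge
    shares = ({"G": ss_gen / geg, "E": ss_env / geg, "GE": ss_ge / geg}
              if geg > 0 else {"G": 0.0, "E": 0.0, "GE": 0.0})
    return AnovaTable(table=tab, shares=shares, g=g, e=e, r=r)


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Make the largest-|.| element of each genotype vector positive so axes
    # are reproducible across LAPACK builds.
    for k in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def fit_ammi(means: pd.DataFrame, r: int, residual_ms: float,
             residual_df: int | None = None) -> AMMIFit:
    """AMMI decomposition of a genotype x environment means table.

    ``r`` is the replicate count behind each cell mean and ``residual_ms``
    the pooled plot-level residual mean square — both needed only for the
    axis F-tests, not for the decomposition itself.
    """
    g, e = means.shape
    if g < 2 or e < 2:
        raise METDataError(f"means table must be at least 2x2, got {g}x{e}")
    y = means.to_numpy(dtype=float)
    grand = float(y.mean())
    alpha = y.mean(axis=1) - grand
    beta = y.mean(axis=0) - grand
    z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand

    p = min(g - 1, e - 1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, v = _fix_signs(u[:, :p].copy(), vt[:p].T.copy())
    lam = s[:p].copy()
    lam[lam < 1e-12 * max(lam[0], 1.0)] = 0.0
    tot = float((lam ** 2).sum())
    ep = lam ** 2 / tot if tot > 0 else np.zeros_like(lam)

    gidx, eidx = list(means.index), list(means.columns)
    return AMMIFit(
        grand_mean=grand,
        genotype_effects=pd.Series(alpha, index=gidx, name="alpha"),
        environment_effects=pd.Series(beta, index=eidx, name="beta"),
        singular_values=lam,
        genotype_vectors=pd.DataFrame(
            u, index=gidx, columns=[f"IPCA{k+1}" for k in range(p)]),
        environment_vectors=pd.DataFrame(
            v, index=eidx, columns=[f"IPCA{k+1}" for k in range(p)]),
        explained=ep,
        r=int(r),
        residual_ms=float(residual_ms),
        residual_df=residual_df,
    )


def fit_ammi_from_dataset(data: METDataset) -> AMMIFit:
    """Joint ANOVA plus AMMI decomposition of a balanced dataset."""
    an = joint_anova(data)
    fit = fit_ammi(cell_means(data), r=an.r, residual_ms=an.residual_ms,
                   residual_df=an.residual_df)
    fit.anova = an
    return fit


def ipca_tests(fit: AMMIFit) -> pd.DataFrame:
    """Per-axis F-tests (Gollob df) and cumulative variance explained.

    SS_k = r * lambda_k^2 (plot basis); df_k = g + e - 1 - 2k; F_k tests
    MS_k against the pooled residual MS.  Axes whose Gollob df is <= 0 are
    reported untestable (NaN F and p).
    """
    g = len(fit.genotype_effects)
    e = len(fit.environment_effects)
    rows = []
    cum = 0.0
    for k in range(1, fit.p + 1):
        lam = fit.singular_values[k - 1]
        ss = fit.r * lam ** 2
        df = g + e - 1 - 2 * k
        cum += float(fit.explained[k - 1]) * 100.0
        if df <= 0:
            rows.append((f"IPCA{k}", ss, df, np.nan, np.nan, np.nan, cum))
            continue
        ms = ss / df
        if fit.residual_ms > 0:
            f = ms / fit.residual_ms
            ddf = fit.residual_df if fit.residual_df else np.inf
            p_val = (float(stats.f.sf(f, df, ddf))
                     if np.isfinite(ddf) else float(stats.chi2.sf(f * df, df)))
        elif ss > 0:
            f, p_val = np.inf, 0.0
        else:
            f, p_val = 0.0, 1.0
        rows.append((f"IPCA{k}", ss, df, ms, f, p_val, cum))
    return pd.DataFrame(
        rows, columns=["axis", "SS", "df", "MS", "F", "p", "cumulative_pct"]
    ).set_index("axis")


def ge_signal_noise(anova: AnovaTable) -> GEPartition:
    """Split the GE sum of squares into noise (df_GE * MS_res) and signal."""
    try:
        ss_ge = float(anova.table.loc["GEN:ENV", "SS"])
        df_ge = float(anova.table.loc["GEN:ENV", "df"])
    except KeyError as exc:
        raise METDataError("ANOVA table lacks a GEN:ENV row") from exc
    noise = min(df_ge * anova.residual_ms, ss_ge)
    signal = ss_ge - noise
    frac = signal / ss_ge if ss_ge > 0 else 0.0
    return GEPartition(ss_ge=ss_ge, noise=noise, signal=signal,
                       signal_fraction=float(np.clip(frac, 0.0, 1.0)))


def predict_ammi(fit: AMMIFit, k: int) -> pd.DataFrame:
    """Cell-mean predictions of the AMMIk model.

    k = 0 is the additive model; k = p reproduces the observed cell means
    to machine precision.
    """
    if not 0 <= k <= fit.p:
        raise METDataError(f"k must be in [0, {fit.p}], got {k}")
    add = (fit.grand_mean
           + fit.genotype_effects.to_numpy()[:, None]
           + fit.environment_effects.to_numpy()[None, :])
    if k > 0:
        u = fit.genotype_vectors.to_numpy()[:, :k]
        v = fit.environment_vectors.to_numpy()[:, :k]
        add = add + (u * fit.singular_values[:k]) @ v.T
    return pd.DataFrame(add, index=fit.genotypes, columns=fit.environments)
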