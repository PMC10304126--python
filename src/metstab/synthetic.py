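"""Synthetic balanced METs (and linked weather) with fully known structure.

The generator draws plot yields from the model every downstream method
assumes:

    y_ger = mu + alpha_g + beta_e + sum_k lambda_k gamma_gk delta_ek
            + ge_ge + b_er + eps_ger

with centered Gaussian genotype and environment main effects, a low-rank
multiplicative interaction on seeded orthonormal centered axes (plus an
optional iid Gaussian interaction term), Gaussian block effects nested in
environments, and Gaussian plot error.  The realized truth — effects,
axes, the full interaction matrix — is returned alongside the data so
recovery can be measured exactly.

The shipped ``pea-like`` preset mimics a Palouse pea trial series: 12
genotypes, 28 environments, 3 blocks, environment-dominated variation
(roughly 0.90 / 0.03 / 0.07 expected shares of the G+E+GE sum of squares)
and an interaction that is about 60% signal.  ``noise-dominated`` has no
real interaction at all, and ``rank1-crossover`` a single strong crossover
axis.  A planted "winner" genotype (large main effect, zero interaction)
can be added to any preset to give stability methods a known target.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .data import METDataError, METDataset

__all__ = [
    "SyntheticTruth",
    "generate_met",
    "generate_from_preset",
    "load_preset",
    "list_presets",
    "generate_weather_yield",
]

PRESETS = ("pea-like", "noise-dominated", "rank1-crossover")


@dataclass
class SyntheticTruth:
    """Realized data-generating values behind one synthetic MET."""

    mu: float
    genotype_effects: pd.Series      # centered
    environment_effects: pd.Series   # centered
    lambdas: np.ndarray
    genotype_axes: np.ndarray        # g x t, orthonormal centered columns
    environment_axes: np.ndarray     # e x t
    ge_matrix: np.ndarray            # g x e, full interaction (axes + iid)
    sigma2_block: float
    sigma2_res: float
    seed: int
    winner: str | None = None        # planted stable high-yielder, if any

    @property
    def expected_cell_means(self) -> pd.DataFrame:
        a = self.genotype_effects.to_numpy()[:, None]
        b = self.environment_effects.to_numpy()[None, :]
        return pd.DataFrame(self.mu + a + b + self.ge_matrix,
                            index=self.genotype_effects.index,
                            columns=self.environment_effects.index)

    @property
    def ge_variance(self) -> float:
        """Interaction SS per interaction degree of freedom."""
        g, e = self.ge_matrix.shape
        return float((self.ge_matrix ** 2).sum() / ((g - 1) * (e - 1)))


def _centered_orthonormal(n: int, t: int, rng: np.random.Generator,
                          zero_row: int | None = None) -> np.ndarray:
    """t orthonormal columns orthogonal to the ones vector.

    If ``zero_row`` is given that row is held at exactly zero (used to
    plant an interaction-free genotype); centering then runs over the
    remaining rows so column sums stay zero.
    """
    if t == 0:
        return np.zeros((n, 0))
    if t > n - 1 - (1 if zero_row is not None else 0):
        raise METDataError(f"cannot fit {t} centered orthonormal axes in "
                           f"{n} rows")
    m = rng.standard_normal((n, t))
    if zero_row is not None:
        m[zero_row] = 0.0
        active = np.ones(n, dtype=bool)
        active[zero_row] = False
        m[active] -= m[active].mean(axis=0)
    else:
        m -= m.mean(axis=0)
    q, rr = np.linalg.qr(m)
    sign = np.sign(np.diag(rr))
    sign[sign == 0] = 1.0
    return q * sign


def generate_met(g: int, e: int, r: int, *,
                 mu: float = 3.0,
                 sigma2_g: float = 0.05,
                 sigma2_e: float = 0.5,
                 lambdas=(),
                 sigma2_ge: float = 0.0,
                 sigma2_block: float = 0.01,
                 sigma2_res: float = 0.1,
                 winner_boost: float | None = None,
                 seed: int = 0) -> tuple[METDataset, SyntheticTruth]:
    """Draw one balanced MET and return it with its generating truth.

    ``lambdas`` are the singular values (cell-mean scale, t/ha) of the
    low-rank interaction; ``sigma2_ge`` adds an independent iid Gaussian
    interaction on top.  ``winner_boost`` plants genotype 1 as a stable
    high-yielder: its main effect is raised by that many t/ha and its
    interaction rows are exactly zero.
    """
    if g < 2 or e < 2 or r < 2:
        raise METDataError(f"need g, e, r >= 2; got g={g}, e={e}, r={r}")
    lam = np.asarray(lambdas, dtype=float)
    t = len(lam)
    if t > min(g - 1, e - 1):
        raise METDataError(f"{t} interaction axes do not fit a "
                           f"{g}x{e} table")
    rng = np.random.default_rng(seed)

    gen_labels = [f"G{i + 1:02d}" for i in range(g)]
    env_labels = [f"E{i + 1:02d}" for i in range(e)]

    alpha = rng.normal(0.0, np.sqrt(sigma2_g), g)
    alpha -= alpha.mean()
    winner = None
    zero_row = None
    if winner_boost is not None:
        zero_row = 0
        winner = gen_labels[0]
        alpha[0] += winner_boost
        alpha -= alpha.mean()
    beta = rng.normal(0.0, np.sqrt(sigma2_e), e)
    beta -= beta.mean()

    gamma = _centered_orthonormal(g, t, rng, zero_row=zero_row)
    delta = _centered_orthonormal(e, t, rng)
    ge = (gamma * lam) @ delta.T if t else np.zeros((g, e))
    if sigma2_ge > 0:
        iid = rng.normal(0.0, np.sqrt(sigma2_ge), (g, e))
        if zero_row is not None:
            iid[zero_row] = 0.0
        ge = ge + iid

    block = rng.normal(0.0, np.sqrt(sigma2_block), (e, r))
    eps = rng.normal(0.0, np.sqrt(sigma2_res), (g, e, r))
    y = (mu + alpha[:, None, None] + beta[None, :, None]
         + ge[:, :, None] + block[None, :, :] + eps)
    y = np.maximum(y, 0.0)  # yields are physical quantities

    idx = pd.MultiIndex.from_product(
        [gen_labels, env_labels, range(1, r + 1)],
        names=["genotype", "environment", "replicate"])
    df = pd.DataFrame({"yield": y.ravel()}, index=idx).reset_index()
    truth = SyntheticTruth(
        mu=mu,
        genotype_effects=pd.Series(alpha, index=gen_labels, name="alpha"),
        environment_effects=pd.Series(beta, index=env_labels, name="beta"),
        lambdas=lam,
        genotype_axes=gamma,
        environment_axes=delta,
        ge_matrix=ge,
        sigma2_block=sigma2_block,
        sigma2_res=sigma2_res,
        seed=int(seed),
        winner=winner,
    )
    return METDataset(df), truth


def list_presets() -> tuple[str, ...]:
    return PRESETS


def load_preset(name: str) -> dict:
    """Load a named generator preset from the shipped config files."""
    if name not in PRESETS:
        raise METDataError(f"unknown preset {name!r}; available: {PRESETS}")
    fname = name.replace("-", "_") + ".yaml"
    ref = resources.files("metstab") / "data" / "presets" / fname
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


def generate_from_preset(name: str, seed: int = 0,
                         **overrides) -> tuple[METDataset, SyntheticTruth]:
    """Generate a MET from a shipped preset, optionally overriding fields."""
    cfg = load_preset(name)
    cfg.update(overrides)
    g, e, r = cfg.pop("g"), cfg.pop("e"), cfg.pop("r")
    return generate_met(g, e, r, seed=seed, **cfg)


def generate_weather_yield(environments: int, effects: dict[str, float],
                           seed: int = 0, *,
                           base_yield: float = 3.0,
                           sigma_y: float = 0.15
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Daily May-August weather plus environment mean yields.

    Each environment gets its own year of daily maximum temperature
    (degrees F, seasonal baseline plus an environment-level anomaly and
    daily noise) and rainfall (wet-day process, mm).  Yields are then
    built as ``base_yield`` plus the specified linear ``effects`` applied
    to the *standardized* aggregated covariates, plus Gaussian noise — so
    the planted covariate-yield associations are known by construction.

    ``effects`` keys must be covariate names produced by
    :func:`metstab.weather.aggregate_weather` (e.g. ``"MaxTJune2": -0.4``);
    an unknown name is an infeasible specification and raises.
    """
    from .weather import aggregate_weather

    if environments < 3:
        raise METDataError("need at least 3 environments")
    rng = np.random.default_rng(seed)
    month_base = {5: 65.0, 6: 75.0, 7: 88.0, 8: 86.0}
    frames = []
    for i in range(environments):
        year = 2001 + i
        env = f"E{year}"
        t_anom = rng.normal(0.0, 5.0)
        wet_logit = rng.normal(-1.0, 0.7)
        wet_p = 1.0 / (1.0 + np.exp(-wet_logit))
        dates, tmax, rain = [], [], []
        for m in (5, 6, 7, 8):
            import calendar
            for d in range(1, calendar.monthrange(year, m)[1] + 1):
                dates.append(f"{year}-{m:02d}-{d:02d}")
                tmax.append(month_base[m] + t_anom + rng.normal(0.0, 4.0))
                wet = rng.random() < wet_p
                rain.append(float(rng.gamma(2.0, 3.0)) if wet else 0.0)
        frames.append(pd.DataFrame(
            {"ENV": env, "DATE": dates,
             "TMAX": np.round(tmax, 1), "RAIN": np.round(rain, 2)}))
    daily = pd.concat(frames, ignore_index=True)

    X = aggregate_weather(daily)
    unknown = sorted(set(effects) - set(X.columns))
    if unknown:
        raise METDataError(
            f"effect spec names unknown covariates: {unknown}")
    y = pd.Series(base_yield, index=X.index, name="mean_yield", dtype=float)
    for name, beta in effects.items():
        col = X[name]
        sd = col.std(ddof=1)
        if sd == 0:
            raise METDataError(
                f"covariate {name!r} is constant; effect infeasible")
        y = y + beta * (col - col.mean()) / sd
    y = y + rng.normal(0.0, sigma_y, len(y))
    return daily, y
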