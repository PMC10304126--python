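"""Weather covariates and their relation to environment mean yield.

Daily records (maximum temperature and rainfall) for each environment's
growing season are aggregated into the covariate set used to explain
yield differences among environments: each month is split into days 1-10,
11-20 and 21 to month-end, with period *averages* for temperature and
period *totals* for rainfall; for June and July two stress counters are
added — the number of rainless days (RF0) and the number of hot days with
maximum temperature at or above a threshold (MaxT>90, 90 degrees
Fahrenheit by default).

Variable names follow the MaxT/RF convention: ``MaxTMay1`` = mean maximum
temperature over the first ten days of May, ``RFJune3`` = total rainfall
from June 21 on, ``RF0June`` and ``MaxT>90July`` the counters.

Environment mean yields are then screened variable-by-variable with
Pearson correlation and jointly with partial least squares regression
(PLSR), which tolerates many collinear predictors; the standardized PLSR
coefficients give the direction and relative size of each weather
driver's association with yield.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .data import METDataError

__all__ = [
    "PLSRResult",
    "aggregate_weather",
    "pearson_screen",
    "plsr_fit",
]

_MONTH = {5: "May", 6: "June", 7: "July", 8: "August"}


@dataclass
class PLSRResult:
    """Standardized PLSR coefficients and univariate screens."""

    coefficients: pd.Series   # per variable, standardized-X scale
    pearson_r: pd.Series      # per variable
    n_components: int
    dropped: list[str] = field(default_factory=list)


def _periods(year: int, month: int) -> list[tuple[int, range]]:
    last = calendar.monthrange(year, month)[1]
    return [(1, range(1, 11)), (2, range(11, 21)), (3, range(21, last + 1))]


def aggregate_weather(daily: pd.DataFrame,
                      months=(5, 6, 7),
                      hot_threshold: float = 90.0,
                      count_months=(6, 7)) -> pd.DataFrame:
    """Build the environment x covariate matrix from daily records.

    ``daily`` needs columns ENV, DATE, TMAX, RAIN; dates must fall in the
    environment's own year.  A period with any missing day yields NaN for
    its covariates (flagged missing rather than silently short-summed);
    the RF0/MaxT>90 counters require the full month.
    """
    req = {"ENV", "DATE", "TMAX", "RAIN"}
    if not req.issubset(daily.columns):
        raise METDataError(f"daily weather needs columns {sorted(req)}")
    df = daily.copy()
    df["DATE"] = pd.to_datetime(df["DATE"])
    rows = {}
    for env, sub in df.groupby("ENV"):
        years = sub["DATE"].dt.year.unique()
        if len(years) != 1:
            raise METDataError(
                f"environment {env!r} has records from several years: "
                f"{sorted(years)}")
        year = int(years[0])
        by_day = sub.set_index(sub["DATE"].dt.strftime("%m-%d"))
        if by_day.index.duplicated().any():
            raise METDataError(f"duplicate dates for environment {env!r}")
        vals: dict[str, float] = {}
        for m in months:
            name = _MONTH[m]
            for pnum, days in _periods(year, m):
                keys = [f"{m:02d}-{d:02d}" for d in days]
                chunk = by_day.reindex(keys)
                complete = chunk["TMAX"].notna().all() and \
                    chunk["RAIN"].notna().all()
                vals[f"MaxT{name}{pnum}"] = (
                    float(chunk["TMAX"].mean()) if complete else np.nan)
                vals[f"RF{name}{pnum}"] = (
                    float(chunk["RAIN"].sum()) if complete else np.nan)
        for m in count_months:
            name = _MONTH[m]
            last = calendar.monthrange(year, m)[1]
            keys = [f"{m:02d}-{d:02d}" for d in range(1, last + 1)]
            chunk = by_day.reindex(keys)
            if chunk["RAIN"].notna().all():
                vals[f"RF0{name}"] = float((chunk["RAIN"] == 0).sum())
            else:
                vals[f"RF0{name}"] = np.nan
            if chunk["TMAX"].notna().all():
                vals[f"MaxT>90{name}"] = float(
                    (chunk["TMAX"] >= hot_threshold).sum())
            else:
                vals[f"MaxT>90{name}"] = np.nan
        rows[env] = vals
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "ENV"
    return out


def pearson_screen(X: pd.DataFrame, y: pd.Series) -> pd.Series:
    """Pearson r of each covariate with environment mean yield.

    Pairwise-complete over environments; a zero-variance column gives NaN.
    """
    y = pd.Series(y).reindex(X.index)
    if len(X) < 3:
        raise METDataError("Pearson screen needs >= 3 environments")
    out = {}
    for col in X.columns:
        pair = pd.concat([X[col], y], axis=1).dropna()
        if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or \
                pair.iloc[:, 1].std() == 0:
            out[col] = np.nan
            continue
        out[col] = float(stats.pearsonr(pair.iloc[:, 0],
                                        pair.iloc[:, 1]).statistic)
    return pd.Series(out, name="pearson_r")


def plsr_fit(X: pd.DataFrame, y: pd.Series,
             n_components: int = 2) -> PLSRResult:
    """PLSR of environment mean yield on autoscaled weather covariates.

    Columns are standardized to zero mean, unit variance and y is
    centered; constant columns are dropped with a warning.  Coefficients
    are on the standardized-predictor scale (t/ha per SD of the
    covariate), directly comparable across variables.
    """
    y = pd.Series(y, dtype=float).reindex(X.index)
    keep = pd.concat([X, y.rename("_y")], axis=1).dropna()
    if len(keep) < n_components + 1:
        raise METDataError(
            f"need >= {n_components + 1} complete environments, "
            f"have {len(keep)}")
    Xc = keep.drop(columns="_y")
    yv = keep["_y"].to_numpy()
    dropped = [c for c in Xc.columns if Xc[c].std(ddof=1) == 0]
    if dropped:
        warn(f"dropping constant covariate(s): {dropped}", stacklevel=2)
        Xc = Xc.drop(columns=dropped)
    if Xc.shape[1] == 0:
        raise METDataError("no non-constant covariates left")
    Xs = (Xc - Xc.mean()) / Xc.std(ddof=1)
    yc = yv - yv.mean()
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(Xs.to_numpy(), yc)
    coef = np.asarray(model.coef_).reshape(-1)
    return PLSRResult(
        coefficients=pd.Series(coef, index=Xc.columns, name="plsr_coef"),
        pearson_r=pearson_screen(Xc, keep["_y"]),
        n_components=n_components,
        dropped=dropped,
    )
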