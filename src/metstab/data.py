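"""Trial data model and long-format CSV I/O.

A multi-environment trial (MET) is held as a tidy table of plot records:
one row per (genotype, environment, replicate) with a seed-yield value.
An *environment* is one location-year combination, written as a location
code followed by a four-digit year (``PU2018`` = Pullman, 2018).  Replicate
labels are blocks of a randomized complete block design and are local to
their environment: block 1 in ``PU2018`` has nothing to do with block 1 in
``FF2016``.

All model-fitting downstream requires a *balanced* dataset — every
(genotype, environment, replicate) cell present exactly once — mirroring
how balanced subsets are extracted from a breeding program's historical
trial series before AMMI/BLUP analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "METDataset",
    "METDataError",
    "FormatError",
    "BalanceError",
    "DegeneracyError",
    "read_long_csv",
    "read_wide_csv",
    "cell_means",
    "parse_dataset_spec",
    "subset_balanced",
    "DEFAULT_COLUMNS",
    "LOCATIONS",
]

#: Default CSV header names for the four canonical columns.
DEFAULT_COLUMNS: dict[str, str] = {
    "genotype": "GEN",
    "environment": "ENV",
    "replicate": "REP",
    "yield": "YIELD",
}

#: Trial-site registry: location code -> site name (Palouse region, WA/ID).
LOCATIONS: dict[str, str] = {
    "DA": "Dayton",
    "FF": "Fairfield",
    "GE": "Genesee",
    "GF": "Garfield",
    "PU": "Pullman",
    "SJ": "St. John",
}

_ENV_PATTERN = re.compile(r"^[A-Za-z]+\d+$")


class METDataError(ValueError):
    """Base error for trial-data problems."""


class FormatError(METDataError):
    """Malformed input file or record."""


class BalanceError(METDataError):
    """Operation requires a balanced dataset."""


class DegeneracyError(METDataError):
    """Data carry no usable variation for the requested model."""


@dataclass(frozen=True)
class TrialRecord:
    """A single plot observation."""

    genotype: str
    environment: str
    replicate: int
    yield_t_ha: float

    def __post_init__(self) -> None:
        if self.yield_t_ha < 0:
            raise FormatError(f"negative yield {self.yield_t_ha} for "
                              f"{self.genotype}/{self.environment}")
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1, got {self.replicate}")
        if not _ENV_PATTERN.match(self.environment):
            raise FormatError(
                f"environment {self.environment!r} does not match "
                "<letters><year> (e.g. PU2018)")


class METDataset:
    """Plot-level records of one multi-environment trial series.

    Parameters
    ----------
    records
        Tidy DataFrame with columns ``genotype``, ``environment``,
        ``replicate``, ``yield`` (canonical names), or an iterable of
        :class:`TrialRecord`.

    Raises
    ------
    FormatError
        On a duplicated (genotype, environment, replicate) triple or an
        invalid field value.
    """

    COLUMNS = ("genotype", "environment", "replicate", "yield")

    def __init__(self, records: pd.DataFrame | Iterable[TrialRecord]):
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, list(self.COLUMNS)].copy()
        else:
            df = pd.DataFrame(
                [(t.genotype, t.environment, t.replicate, t.yield_t_ha)
                 for t in records],
                columns=list(self.COLUMNS),
            )
        if df.empty:
            raise FormatError("dataset has no records")
        df["genotype"] = df["genotype"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["yield"] = df["yield"].astype(float)
        self._validate(df)
        self._df = df.reset_index(drop=True)
        self._genotypes = tuple(sorted(df["genotype"].unique()))
        self._environments = tuple(sorted(df["environment"].unique()))
        self._replicates = tuple(sorted(df["replicate"].unique()))

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["yield"] < 0).any():
            bad = df.index[df["yield"] < 0][0]
            raise FormatError(f"negative yield at record {bad}")
        if (df["replicate"] < 1).any():
            raise FormatError("replicate labels must be >= 1")
        bad_env = [e for e in df["environment"].unique()
                   if not _ENV_PATTERN.match(e)]
        if bad_env:
            raise FormatError(
                f"environment identifiers not of form <letters><year>: "
                f"{bad_env[:5]}")
        dup = df.duplicated(subset=["genotype", "environment", "replicate"])
        if dup.any():
            g, e, r = df.loc[dup.idxmax(),
                             ["genotype", "environment", "replicate"]]
            raise FormatError(
                f"duplicate plot record for ({g}, {e}, rep {r})")

    # -- basic shape ---------------------------------------------------

    @property
    def records(self) -> pd.DataFrame:
        """Copy of the tidy record table."""
        return self._df.copy()

    @property
    def genotypes(self) -> tuple[str, ...]:
        return self._genotypes

    @property
    def environments(self) -> tuple[str, ...]:
        return self._environments

    @property
    def replicates(self) -> tuple[int, ...]:
        return self._replicates

    @property
    def g(self) -> int:
        return len(self._genotypes)

    @property
    def e(self) -> int:
        return len(self._environments)

    @property
    def r(self) -> int:
        return len(self._replicates)

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "balanced" if self.is_balanced else "unbalanced"
        return (f"METDataset(g={self.g}, e={self.e}, r={self.r}, "
                f"n={len(self)}, {tag})")

    # -- balance -------------------------------------------------------

    @property
    def is_balanced(self) -> bool:
        return (len(self._df) == self.g * self.e * self.r
                and not self.missing_cells())

    def missing_cells(self) -> list[tuple[str, str, int]]:
        """(genotype, environment, replicate) triples absent from the data."""
        have = set(map(tuple, self._df[
            ["genotype", "environment", "replicate"]].itertuples(index=False)))
        return [(g, e, r)
                for g in self._genotypes
                for e in self._environments
                for r in self._replicates
                if (g, e, r) not in have]

    def require_balanced(self, what: str = "this analysis") -> None:
        if not self.is_balanced:
            missing = self.missing_cells()
            raise BalanceError(
                f"{what} requires a balanced dataset; "
                f"{len(missing)} cell(s) missing, first: {missing[:3]}. "
                "Use subset_balanced() to extract a complete block.")

    # -- views ---------------------------------------------------------

    def to_array(self) -> np.ndarray:
        """Balanced data as a ``(g, e, r)`` array in sorted label order."""
        self.require_balanced("array layout")
        idx = pd.MultiIndex.from_product(
            [self._genotypes, self._environments, self._replicates])
        s = self._df.set_index(
            ["genotype", "environment", "replicate"])["yield"]
        return s.reindex(idx).to_numpy().reshape(self.g, self.e, self.r)

    def environment_subset(self, environment: str) -> pd.DataFrame:
        sub = self._df[self._df["environment"] == environment]
        if sub.empty:
            raise METDataError(f"environment {environment!r} not in dataset")
        return sub.copy()

    def write_long_csv(self, path: str | Path,
                       columns: Mapping[str, str] | None = None) -> None:
        """Write the tidy table, default header GEN, ENV, REP, YIELD."""
        colmap = dict(DEFAULT_COLUMNS)
        if columns:
            colmap.update(columns)
        out = self._df.rename(columns={k: colmap[k] for k in self.COLUMNS})
        out.to_csv(path, index=False)


def read_long_csv(path: str | Path,
                  columns: Mapping[str, str] | None = None) -> METDataset:
    """Read a tidy plot-level trial CSV.

    Parameters
    ----------
    path
        CSV with one row per plot.
    columns
        Optional mapping from canonical names (``genotype``, ``environment``,
        ``replicate``, ``yield``) to the file's header names; defaults to
        GEN, ENV, REP, YIELD.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, comment="#")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing}; found "
            f"{list(df.columns)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    bad = pd.to_numeric(df["yield"], errors="coerce").isna() & df["yield"].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise FormatError(
            f"{path.name}: non-numeric yield at line {row}: "
            f"{df.loc[bad.idxmax(), 'yield']!r}")
    df["yield"] = pd.to_numeric(df["yield"])
    if df["yield"].isna().any():
        row = int(df["yield"].isna().idxmax()) + 2
        raise FormatError(f"{path.name}: empty yield at line {row}")
    return METDataset(df)


def read_wide_csv(path: str | Path) -> pd.DataFrame:
    """Read a genotype x environment means table (first column = genotype).

    Accepted for means-only analyses (AMMI/GGE on cell means) when only a
    summary table is published; the replicate count must then be supplied
    separately to any operation that needs a plot basis.
    """
    df = pd.read_csv(path, comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def cell_means(data: METDataset) -> pd.DataFrame:
    """Genotype x environment table of cell means over replicates.

    The grand mean of the table equals the grand mean of the plot records
    (balance is required, so every cell averages the same number of plots).
    """
    data.require_balanced("cell means")
    tab = data.records.pivot_table(index="genotype", columns="environment",
                                   values="yield", aggfunc="mean")
    return tab.loc[list(data.genotypes), list(data.environments)]


_SEGMENT = re.compile(r"([A-Za-z][A-Za-z,\s]*?)\s*\(([^()]*)\)")
_YEAR_RANGE = re.compile(r"^(\d{4})\s*[-–—]\s*(\d{4})$")


def parse_dataset_spec(spec: str,
                       locations: Mapping[str, str] | None = None
                       ) -> list[str]:
    """Expand a dataset-specification string into environment identifiers.

    The notation lists location codes followed by a parenthesised year list,
    e.g. ``"DA, FF, and PU (2012-2018), GE (2012, 2014-2018), GF (2012)"``.
    Years may be single or ranges (inclusive); ranges accept ``-`` or an
    en-dash.  Output is de-duplicated and sorted.

    Raises
    ------
    FormatError
        On an unknown location code or an unparseable segment.
    """
    known = dict(LOCATIONS if locations is None else locations)
    segments = _SEGMENT.findall(spec)
    if not segments:
        raise FormatError(f"no location(year) segments found in {spec!r}")
    envs: set[str] = set()
    for codes_part, years_part in segments:
        codes = [c for c in re.findall(r"[A-Za-z]+", codes_part)
                 if c.lower() != "and"]
        if not codes:
            raise FormatError(f"no location codes in segment {codes_part!r}")
        for code in codes:
            if code not in known:
                raise FormatError(
                    f"unknown location code {code!r}; known: "
                    f"{sorted(known)}")
        years: list[int] = []
        for item in years_part.split(","):
            item = item.strip()
            if not item:
                continue
            m = _YEAR_RANGE.match(item)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if hi < lo:
                    raise FormatError(f"bad year range {item!r}")
                years.extend(range(lo, hi + 1))
            elif re.fullmatch(r"\d{4}", item):
                years.append(int(item))
            else:
                raise FormatError(f"unparseable year entry {item!r}")
        if not years:
            raise FormatError(f"no years for segment {codes_part!r}")
        envs.update(f"{c}{y}" for c in codes for y in years)
    return sorted(envs)


def subset_balanced(data: METDataset,
                    genotypes: Sequence[str] | None = None,
                    environments: Sequence[str] | None = None) -> METDataset:
    """Extract a user-specified balanced block from a larger trial series.

    Filters to the given genotype/environment lists (defaults: keep all) and
    verifies the result is balanced; the caller chooses the block, typically
    the genotypes tested commonly across a span of environments.
    """
    df = data.records
    if genotypes is not None:
        missing = set(genotypes) - set(data.genotypes)
        if missing:
            raise METDataError(f"genotypes not in dataset: {sorted(missing)}")
        df = df[df["genotype"].isin(genotypes)]
    if environments is not None:
        missing = set(environments) - set(data.environments)
        if missing:
            raise METDataError(
                f"environments not in dataset: {sorted(missing)}")
        df = df[df["environment"].isin(environments)]
    sub = METDataset(df)
    sub.require_balanced("the requested subset")
    return sub
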