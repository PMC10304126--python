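"""Packaged reference inputs from the USDA-ARS Palouse pea trial series.

Two small published summaries of a decade (2012-2021) of pea advanced
yield trials (green, yellow and autumn-sown winter market classes) run by
the USDA-ARS grain legume breeding program around Pullman, WA, ship with
the package:

* per-environment mean seed yield (t/ha) and trial CV (%) for each market
  class, used for the class-comparison and yield-reduction summaries;
* the specification strings of the six balanced analysis datasets that
  were extracted from the series (location codes plus year lists), used to
  exercise the dataset-spec parser.

These are summary-level inputs; the underlying plot data are not public,
which is why the :mod:`metstab.synthetic` generator exists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_pea_environment_means",
    "PEA_DATASET_SPECS",
    "PEA_DATASET_SIZES",
]

#: Specification strings of the six balanced pea datasets:
#: name -> (market class, environment spec, number of genotypes).
PEA_DATASET_SPECS: dict[str, tuple[str, str, int]] = {
    "Green1218": ("green",
                  "DA, FF, and PU (2012-2018), GE (2012, 2014-2018), "
                  "GF (2012)", 12),
    "Green1820": ("green", "DA, FF, GE, and PU (2018-2020)", 9),
    "Yellow1216": ("yellow",
                   "FF and PU (2012-2016), GE (2012, 2014, 2015), "
                   "GF (2012)", 8),
    "Yellow1720": ("yellow", "FF and PU (2017-2020), GE (2017)", 10),
    "Winter1417": ("winter",
                   "GF and PU (2014, 2016, 2017), DA (2014, 2017), "
                   "GE (2014, 2016)", 10),
    "Winter1921": ("winter", "PU (2019-2021), GE and SJ (2019, 2021)", 15),
}

#: name -> (environments, genotypes) as published.
PEA_DATASET_SIZES: dict[str, tuple[int, int]] = {
    "Green1218": (28, 12),
    "Green1820": (12, 9),
    "Yellow1216": (14, 8),
    "Yellow1720": (9, 10),
    "Winter1417": (10, 10),
    "Winter1921": (7, 15),
}


def load_pea_environment_means() -> pd.DataFrame:
    """Published per-environment mean yield and CV for the three classes.

    Returns a DataFrame indexed by environment with columns
    ``{GREEN,YELLOW,WINTER}_MEAN`` (t/ha) and ``..._CV`` (%); a class
    absent from an environment is NaN.
    """
    ref = resources.files("metstab") / "data" / "pea_env_class_means.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="ENV")
    return df.astype(float)


def class_mean_table() -> pd.DataFrame:
    """Environment x market-class table of mean yields (t/ha)."""
    df = load_pea_environment_means()
    out = df[["GREEN_MEAN", "YELLOW_MEAN", "WINTER_MEAN"]].copy()
    out.columns = ["green", "yellow", "winter"]
    return out
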