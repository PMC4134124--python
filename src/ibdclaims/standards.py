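"""Standard populations for direct age standardization.

The bundled standard is the 2006 Canadian census population, the usual
reference for Canadian chronic-disease incidence reporting of this era.
Counts are by five-year age group, both sexes, from Statistics Canada's 2006
Census of Population (age and sex release, catalogue 97-551; StatCan publishes
census counts rounded to the nearest 5).  Only the normalized weights enter
any computation, so nearest-5 rounding is immaterial.

A user-supplied standard may be loaded from CSV with columns
``age_group,weight`` (weights are renormalized to sum to 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .age_groups import AgeGrouping
from .errors import ConfigurationError

CANADA_2006_FIVE_YEAR_COUNTS: dict[str, int] = {
    "0-4": 1_690_550,
    "5-9": 1_810_175,
    "10-14": 2_079_465,
    "15-19": 2_133_610,
    "20-24": 2_075_470,
    "25-29": 1_984_165,
    "30-34": 2_084_120,
    "35-39": 2_265_190,
    "40-44": 2_538_705,
    "45-49": 2_475_395,
    "50-54": 2_314_075,
    "55-59": 2_040_570,
    "60-64": 1_584_180,
    "65-69": 1_224_625,
    "70-74": 1_038_585,
    "75-79": 902_560,
    "80-84": 674_360,
    "85+": 516_695,
}


def canada_2006_weights(grouping: AgeGrouping) -> pd.Series:
    """Standard weights for ``grouping`` aggregated from the 5-year census bands.

    Every bin boundary of ``grouping`` must be a multiple of 5 so the census
    bands nest exactly.
    """
    bad = [lo for lo in grouping.lowers if lo % 5]
    if bad:
        raise ConfigurationError(
            f"canada_2006 standard requires 5-year-aligned bins; offending lower bounds {bad}"
        )
    band_lowers = np.array([int(lab.split("-")[0].rstrip("+")) for lab in CANADA_2006_FIVE_YEAR_COUNTS])
    counts = np.array(list(CANADA_2006_FIVE_YEAR_COUNTS.values()), dtype=float)
    idx = grouping.index_of(band_lowers)
    agg = np.zeros(grouping.n_bins)
    np.add.at(agg, idx, counts)
    weights = pd.Series(agg / agg.sum(), index=list(grouping.labels), name="weight")
    weights.index.name = "age_group"
    return weights


def load_standard_csv(path: str | Path, grouping: AgeGrouping | None = None) -> pd.Series:
    """Read ``age_group,weight`` CSV; optionally check coverage of a grouping."""
    df = pd.read_csv(path)
    for col in ("age_group", "weight"):
        if col not in df.columns:
            raise ConfigurationError(f"standard population file {path} lacks column {col!r}")
    s = df.set_index("age_group")["weight"].astype(float)
    if (s < 0).any():
        raise ConfigurationError(f"standard population file {path} has negative weights")
    if grouping is not None:
        missing = set(grouping.labels) - set(s.index)
        if missing:
            raise ConfigurationError(
                f"standard population file {path} missing age groups {sorted(missing)}"
            )
        s = s.reindex(list(grouping.labels))
    return s / s.sum()
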