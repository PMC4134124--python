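"""Contiguous age-group binnings and conversions between them.

Two groupings are used throughout: decade bins (``<10`` ... ``80+``) for case
tabulation and age-standardized rates, and coarser trend bins (``<20`` ...
``50+``) for the stratified Poisson trend models.  A grouping is an ordered
partition of ``[0, inf)`` defined by its bin lower bounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, CoverageError

_RANGE = re.compile(r"^(\d+)\s*-\s*(\d+)$")
_UNDER = re.compile(r"^<\s*(\d+)$")
_OVER = re.compile(r"^(?:≥\s*(\d+)|(\d+)\s*\+)$")


@dataclass(frozen=True)
class AgeGrouping:
    """An ordered, contiguous, non-overlapping partition of ages 0..inf."""

    lowers: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lowers) != len(self.labels) or not self.lowers:
            raise ConfigurationError("age grouping: lowers and labels must match and be non-empty")
        if self.lowers[0] != 0:
            raise ConfigurationError("age grouping: first bin must start at age 0")
        if any(b <= a for a, b in zip(self.lowers, self.lowers[1:])):
            raise ConfigurationError("age grouping: bin lower bounds must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.lowers)

    def index_of(self, ages) -> np.ndarray:
        """Bin index for each age (top bin is open-ended)."""
        ages = np.asarray(ages)
        if ages.size and ages.min() < 0:
            raise ValueError("negative age")
        return np.searchsorted(self.lowers, ages, side="right") - 1

    def label_of(self, ages) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)[self.index_of(ages)]

    @classmethod
    def from_labels(cls, labels) -> "AgeGrouping":
        """Parse labels like ``<10``, ``10-19``, ``80+`` / ``≥80`` into bins.

        Bins must be contiguous: each label's implied upper bound must equal
        the next label's lower bound.
        """
        lowers: list[int] = []
        uppers: list[int | None] = []
        for lab in labels:
            lab = str(lab).strip()
            if m := _UNDER.match(lab):
                lowers.append(0)
                uppers.append(int(m.group(1)))
            elif m := _RANGE.match(lab):
                lowers.append(int(m.group(1)))
                uppers.append(int(m.group(2)) + 1)
            elif m := _OVER.match(lab):
                lowers.append(int(m.group(1) or m.group(2)))
                uppers.append(None)
            else:
                raise ConfigurationError(f"age grouping: cannot parse label {lab!r}")
        for i, up in enumerate(uppers[:-1]):
            if up is None or up != lowers[i + 1]:
                raise ConfigurationError(
                    f"age grouping: bins {labels[i]!r} and {labels[i + 1]!r} are not contiguous"
                )
        if uppers[-1] is not None:
            raise ConfigurationError("age grouping: last bin must be open-ended (e.g. '80+')")
        return cls(tuple(lowers), tuple(str(x) for x in labels))


DECADE_BINS = AgeGrouping.from_labels(
    ("<10", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
)
TREND_BINS = AgeGrouping.from_labels(("<20", "20-29", "30-39", "40-49", "50+"))


def regroup_map(fine: AgeGrouping, coarse: AgeGrouping) -> dict[str, str]:
    """Map each fine bin label to the coarse bin that contains it.

    Every coarse boundary must also be a fine boundary, otherwise the fine
    bins straddle coarse ones and exact regrouping is impossible.
    """
    missing = set(coarse.lowers) - set(fine.lowers)
    if missing:
        raise CoverageError(f"cannot regroup: coarse boundaries {sorted(missing)} not in fine bins")
    idx = coarse.index_of(np.asarray(fine.lowers))
    return {fl: coarse.labels[i] for fl, i in zip(fine.labels, idx)}
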