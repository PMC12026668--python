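"""Daily discrimination index: non-vaccinated minus vaccinated composite index.

For a country with non-vaccinated index series NV(t) and vaccinated series
V(t) on the same basis (CHI or Stringency),

    D(t) = NV(t) - V(t)

so D(t) = 0 on days without any status-differentiated policy and D(t) > 0
when restrictions bind the non-vaccinated more tightly. Values are bounded
in [-100, 100]; negative values (the vaccinated restricted more) are
preserved and logged as anomalies, never clipped.

The study window stacks the 2021 and 2022 calendar years on one continuous
daily axis (730 days; neither year has a leap day).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import INDEX_NAMES
from .index_engine import IndexSeries, NON_VACCINATED, VACCINATED

__all__ = [
    "STUDY_START",
    "STUDY_END",
    "STUDY_DAYS",
    "study_window",
    "DiscriminationSeries",
    "discrimination_series",
    "stack_years",
]

logger = logging.getLogger(__name__)

STUDY_START = pd.Timestamp("2021-01-01")
STUDY_END = pd.Timestamp("2022-12-31")
STUDY_DAYS = 730


def study_window() -> pd.DatetimeIndex:
    """The stacked 2021–2022 daily axis (730 days)."""
    return pd.date_range(STUDY_START, STUDY_END, freq="D")


@dataclass
class DiscriminationSeries:
    """Daily discrimination values D(t) for one country on one index basis."""

    country_code: str
    country_name: str
    index_basis: str
    values: pd.Series

    def __post_init__(self):
        if self.index_basis not in INDEX_NAMES:
            raise ValueError(f"unknown index_basis {self.index_basis!r}")
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise TypeError("values must be indexed by dates")
        if len(v) and not v.index.equals(
            pd.date_range(v.index[0], v.index[-1], freq="D")
        ):
            raise ValueError(
                f"{self.country_code}: discrimination axis has gaps, duplicates, "
                "or is unsorted"
            )
        arr = v.to_numpy(dtype=float)
        if (np.abs(arr) > 100).any():
            raise ValueError(f"{self.country_code}: |D| exceeds 100")

    def __len__(self) -> int:
        return len(self.values)


def discrimination_series(nv: IndexSeries, v: IndexSeries) -> DiscriminationSeries:
    """Pointwise difference D(t) = nv(t) - v(t) on the shared date axis."""
    if nv.country_code != v.country_code:
        raise ValueError(
            f"country mismatch: {nv.country_code!r} vs {v.country_code!r}"
        )
    if nv.index_name != v.index_name:
        raise ValueError(f"basis mismatch: {nv.index_name!r} vs {v.index_name!r}")
    if nv.status_group != NON_VACCINATED or v.status_group != VACCINATED:
        raise ValueError(
            "expected a non_vaccinated series and a vaccinated series, got "
            f"{nv.status_group!r} and {v.status_group!r}"
        )
    if not nv.values.index.equals(v.values.index):
        raise ValueError(f"{nv.country_code}: date axes differ")
    d = nv.values - v.values
    n_neg = int((d.to_numpy() < 0).sum())
    if n_neg:
        logger.warning(
            "%s: %d days with negative discrimination (vaccinated restricted "
            "more); preserved, not clipped", nv.country_code, n_neg,
        )
    return DiscriminationSeries(
        country_code=nv.country_code,
        country_name=nv.country_name,
        index_basis=nv.index_name,
        values=d,
    )


def stack_years(
    series_2021: DiscriminationSeries, series_2022: DiscriminationSeries
) -> DiscriminationSeries:
    """Concatenate two annual series onto one continuous daily axis.

    The second series must start exactly one day after the first ends;
    overlaps, gaps or an empty year are hard errors.
    """
    a, b = series_2021, series_2022
    if a.country_code != b.country_code:
        raise ValueError(f"country mismatch: {a.country_code!r} vs {b.country_code!r}")
    if a.index_basis != b.index_basis:
        raise ValueError(f"basis mismatch: {a.index_basis!r} vs {b.index_basis!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"{a.country_code}: both annual series must be non-empty to stack"
        )
    expected = a.values.index[-1] + pd.Timedelta(days=1)
    if b.values.index[0] != expected:
        kind = "overlap" if b.values.index[0] <= a.values.index[-1] else "gap"
        raise ValueError(
            f"{a.country_code}: {kind} at the year boundary — second series "
            f"starts {b.values.index[0].date()}, expected {expected.date()}"
        )
    return DiscriminationSeries(
        country_code=a.country_code,
        country_name=a.country_name or b.country_name,
        index_basis=a.index_basis,
        values=pd.concat([a.values, b.values]),
    )
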