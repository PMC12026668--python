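"""Per-country summaries of the discrimination index and cross-country views.

Each country is reduced to the mean, median and maximum of its daily
discrimination index over the full stacked 2021–2022 window (all 730
days, including days before any differentiation — long zero stretches are
part of the signal, which is why medians are often 0 and the mean best
combines duration and magnitude). The summary also carries the underlying
average composite index (non-vaccinated basis by default) and the region
labels used for grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .discrimination import DiscriminationSeries, study_window
from .index_engine import IndexSeries
from .oxcgrt_io import CountryRegion

__all__ = [
    "CountrySummary",
    "AssociationResult",
    "ZeroPartition",
    "summarize_country",
    "summaries_to_frame",
    "rank_countries",
    "zero_partition",
    "group_by_region",
    "association",
]

SUMMARY_COLUMNS = [
    "country_code", "country_name", "continent", "sub_region",
    "mean_D", "median_D", "max_D", "mean_CHI", "discriminated",
]


@dataclass(frozen=True)
class CountrySummary:
    country_code: str
    country_name: str
    continent: str
    sub_region: str
    mean_D: float
    median_D: float
    max_D: float
    mean_CHI: float
    discriminated: bool


class AssociationResult(NamedTuple):
    """OLS fit of one summary statistic on another across countries."""

    response: str
    predictor: str
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


class ZeroPartition(NamedTuple):
    """Countries with / without any recorded discrimination, and the
    unweighted mean of per-country average composite index in each set."""

    zero: pd.DataFrame
    nonzero: pd.DataFrame
    zero_mean_chi: float
    nonzero_mean_chi: float


def summarize_country(
    d: DiscriminationSeries,
    chi: IndexSeries,
    region: CountryRegion | None,
    *,
    window: pd.DatetimeIndex | None = None,
    permissive: bool = False,
) -> CountrySummary:
    """Reduce one country's daily series to its summary statistics.

    ``d`` must span the full study window (all days count toward the
    mean/median, including zero-discrimination days); ``permissive``
    accepts a partial window and summarizes over the days present.
    """
    if window is None:
        window = study_window()
    if not permissive and not d.values.index.equals(window):
        raise ValueError(
            f"{d.country_code}: series covers {len(d)} days, expected the "
            f"full {len(window)}-day window (use permissive=True to accept)"
        )
    if chi.country_code != d.country_code:
        raise ValueError(
            f"country mismatch: {d.country_code!r} vs {chi.country_code!r}"
        )
    arr = d.values.to_numpy(dtype=float)
    max_d = float(arr.max())
    return CountrySummary(
        country_code=d.country_code,
        country_name=d.country_name or chi.country_name,
        continent=region.continent if region else "",
        sub_region=region.sub_region if region else "",
        mean_D=float(arr.mean()),
        median_D=float(np.median(arr)),
        max_D=max_d,
        mean_CHI=float(chi.values.to_numpy(dtype=float).mean()),
        discriminated=bool(max_d > 0),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack :class:`CountrySummary` records into a DataFrame (or pass an
    already-assembled frame through unchanged)."""
    if isinstance(summaries, pd.DataFrame):
        return summaries
    rows = [asdict(s) for s in summaries]
    if not rows:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.DataFrame(rows)[SUMMARY_COLUMNS]


def rank_countries(summaries, by: str = "mean_D", n: int = 10) -> pd.DataFrame:
    """Top-*n* countries by ``mean_D`` or ``max_D``, descending; ties broken
    by country code so rankings are reproducible."""
    if by not in ("mean_D", "max_D"):
        raise ValueError(f"rank key must be 'mean_D' or 'max_D', got {by!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    df = summaries_to_frame(summaries)
    out = (
        df.sort_values([by, "country_code"], ascending=[False, True])
        .head(n)
        .reset_index(drop=True)
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def zero_partition(summaries) -> ZeroPartition:
    """Split countries into zero-discrimination and discriminated sets."""
    df = summaries_to_frame(summaries)
    zero = df[~df["discriminated"]].reset_index(drop=True)
    nonzero = df[df["discriminated"]].reset_index(drop=True)
    return ZeroPartition(
        zero=zero,
        nonzero=nonzero,
        zero_mean_chi=float(zero["mean_CHI"].mean()) if len(zero) else float("nan"),
        nonzero_mean_chi=(
            float(nonzero["mean_CHI"].mean()) if len(nonzero) else float("nan")
        ),
    )


def group_by_region(summaries, level: str = "continent") -> pd.DataFrame:
    """Per-continent (or per-sub-region) counts and shares of discriminated
    countries, with group means of the summary statistics."""
    if level not in ("continent", "sub_region"):
        raise ValueError(f"level must be 'continent' or 'sub_region', got {level!r}")
    df = summaries_to_frame(summaries)
    grouped = df.groupby(level, sort=True)
    out = grouped.agg(
        n_countries=("country_code", "size"),
        n_discriminated=("discriminated", "sum"),
        n_zero=("discriminated", lambda s: int((~s).sum())),
        mean_mean_D=("mean_D", "mean"),
        mean_max_D=("max_D", "mean"),
        mean_CHI=("mean_CHI", "mean"),
    ).reset_index()
    out["share_discriminated"] = out["n_discriminated"] / out["n_countries"]
    return out


def association(summaries, response: str, predictor: str) -> AssociationResult:
    """Ordinary least-squares fit of one per-country statistic on another.

    Returns the R², the two-sided p-value of the slope, and the fitted
    line. Requires at least 3 countries and a non-constant predictor.
    """
    df = summaries_to_frame(summaries)
    pair = pd.DataFrame({"y": df[response], "x": df[predictor]}).dropna()
    x = pair["x"].to_numpy(dtype=float)
    y = pair["y"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"association needs >= 3 countries, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance; fit undefined")
    if np.ptp(y) == 0:
        # a constant response is perfectly explained by the intercept
        return AssociationResult(response, predictor, 0.0, 1.0, 0.0,
                                 float(y[0]), len(x))
    fit = stats.linregress(x, y)
    return AssociationResult(
        response=response,
        predictor=predictor,
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )
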