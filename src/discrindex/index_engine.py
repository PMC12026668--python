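"""Composite policy index computation per country, day and status group.

A single indicator's ordinal code ``v`` with geographic-scope flag ``f``
maps to a 0–100 sub-index score

    score = 0                                   if v == 0
    score = 100 * (v - 0.5 * (1 - f)) / N       if the indicator is flagged
    score = 100 * v / N                         otherwise

where ``N`` is the indicator's maximum code. The 0.5 deduction is the
crude correction for measures targeted to a specific region (flag 0)
rather than applied nationwide (flag 1). A composite index (CHI or
Stringency) is the unweighted mean of its member indicators' sub-index
scores, so it also lives on the 0–100 scale.

For each status group (non-vaccinated / vaccinated), a differentiated
indicator contributes its group-specific observation on days when the
jurisdiction differentiated, and the shared value otherwise;
non-differentiated indicators contribute identically to both groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook, INDEX_NAMES

__all__ = [
    "NON_VACCINATED",
    "VACCINATED",
    "SHARED",
    "STATUS_GROUPS",
    "IndexSeries",
    "subindex",
    "composite_index",
    "build_index_series",
]

logger = logging.getLogger(__name__)

NON_VACCINATED = "non_vaccinated"
VACCINATED = "vaccinated"
SHARED = "shared"
STATUS_GROUPS = (NON_VACCINATED, VACCINATED)


@dataclass
class IndexSeries:
    """Daily composite index values for one country and status group.

    ``values`` is a float Series on a contiguous daily DatetimeIndex,
    every value in [0, 100].
    """

    country_code: str
    index_name: str
    status_group: str
    values: pd.Series
    country_name: str = ""

    def __post_init__(self):
        if self.index_name not in INDEX_NAMES:
            raise ValueError(f"unknown index_name {self.index_name!r}")
        if self.status_group not in STATUS_GROUPS:
            raise ValueError(f"unknown status_group {self.status_group!r}")
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise TypeError("values must be indexed by dates")
        if len(v) and not v.index.equals(
            pd.date_range(v.index[0], v.index[-1], freq="D")
        ):
            raise ValueError(
                f"{self.country_code}/{self.status_group}: date axis has gaps, "
                "duplicates, or is unsorted"
            )
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            bad = v.index[np.isnan(arr)][0].date()
            raise ValueError(f"{self.country_code}: missing index value on {bad}")
        if ((arr < 0) | (arr > 100)).any():
            raise ValueError(f"{self.country_code}: index values outside [0, 100]")

    def __len__(self) -> int:
        return len(self.values)


def subindex(code, flag, spec) -> float:
    """Score one indicator observation on the 0–100 scale.

    ``flag`` must be supplied (0 or 1) exactly when ``spec.has_flag``;
    a zero code always scores 0 regardless of flag state.
    """
    code = float(code)
    if not code.is_integer() or not (0 <= code <= spec.max_code):
        raise ValueError(
            f"{spec.id}: code {code} outside ordinal range 0..{spec.max_code}"
        )
    if flag is not None and not spec.has_flag:
        raise ValueError(f"{spec.id}: flag supplied but indicator has no flag")
    if code == 0:
        return 0.0
    if spec.has_flag:
        if flag is None:
            raise ValueError(f"{spec.id}: flag required for positive code")
        if flag not in (0, 1):
            raise ValueError(f"{spec.id}: flag must be 0 or 1, got {flag!r}")
        return 100.0 * (code - 0.5 * (1 - flag)) / spec.max_code
    return 100.0 * code / spec.max_code


def composite_index(
    scores, index_name: str, codebook: Codebook, *, allow_missing: bool = False
) -> float:
    """Unweighted mean of the member indicators' sub-index scores.

    ``scores`` maps indicator id -> sub-index score for one country-day.
    By default every member must be present; with ``allow_missing`` the
    mean is taken over the members that are present (logged).
    """
    members = codebook.members(index_name)
    missing = [m for m in members if m not in scores or scores[m] is None]
    if missing and not allow_missing:
        raise ValueError(f"{index_name}: missing member indicators {missing}")
    present = [m for m in members if m not in missing]
    if not present:
        raise ValueError(f"{index_name}: no member indicators present")
    if missing:
        logger.warning(
            "%s: averaging over %d of %d members (missing %s)",
            index_name, len(present), len(members), missing,
        )
    return float(np.mean(np.array([scores[m] for m in present], dtype=float)))


def _check_contradictions(obs: pd.DataFrame) -> None:
    key = ["country_code", "date", "indicator", "status_group"]
    dup = obs.drop_duplicates(subset=key + ["code"]).duplicated(subset=key, keep=False)
    if dup.any():
        row = obs.drop_duplicates(subset=key + ["code"])[dup].iloc[0]
        raise ValueError(
            "contradictory duplicate observations for "
            f"{row['country_code']}/{row['date'].date()}/{row['indicator']}"
            f"/{row['status_group']}"
        )


def _subindex_matrix(codes: pd.DataFrame, flags: pd.DataFrame, codebook: Codebook,
                     members) -> np.ndarray:
    """Vectorized sub-index scores; columns of *codes* are indicator ids."""
    out = np.empty((len(codes), len(members)), dtype=float)
    for k, iid in enumerate(members):
        spec = codebook[iid]
        v = codes[iid].to_numpy(dtype=float)
        bad = ~np.isnan(v) & ((v < 0) | (v > spec.max_code) | (v != np.floor(v)))
        if bad.any():
            i = int(np.argmax(bad))
            cc, date = codes.index[i]
            raise ValueError(
                f"{cc}/{pd.Timestamp(date).date()}/{iid}: code {v[i]} outside "
                f"ordinal range 0..{spec.max_code}"
            )
        if spec.has_flag:
            f = flags[iid].to_numpy(dtype=float) if iid in flags else np.full_like(v, np.nan)
            unflagged = np.isnan(f) & (v > 0)
            if unflagged.any():
                logger.warning(
                    "%s: %d positive codes without a flag value; treating as "
                    "regionally targeted (flag 0)", iid, int(unflagged.sum()),
                )
            f = np.where(np.isnan(f), 0.0, f)
            s = 100.0 * (v - 0.5 * (1.0 - f)) / spec.max_code
        else:
            s = 100.0 * v / spec.max_code
        out[:, k] = np.where(v == 0, 0.0, s)
    return out


def build_index_series(
    obs: pd.DataFrame,
    codebook: Codebook,
    index_name: str,
    *,
    strict: bool = True,
) -> dict:
    """Compute per-country daily composite index series for both status groups.

    Parameters
    ----------
    obs
        Tidy observations with columns ``country_code, country_name, date,
        indicator, status_group, code, flag`` (flag NaN where absent).
    codebook
        Coding schema; only member indicators of *index_name* are used.
    index_name
        ``"CHI"`` or ``"STRINGENCY"``.
    strict
        If True (default), a country-day missing any member indicator is a
        hard error; if False the composite averages the present members and
        the gap is logged.

    Returns
    -------
    dict mapping ``(country_code, status_group)`` -> :class:`IndexSeries`.
    """
    members = codebook.members(index_name)
    obs = obs[obs["indicator"].isin(members)]
    if obs.empty:
        return {}
    _check_contradictions(obs)
    names = (
        obs.groupby("country_code")["country_name"].first()
        if "country_name" in obs
        else pd.Series(dtype=object)
    )

    shared = obs[obs["status_group"] == SHARED]
    out = {}
    for group in STATUS_GROUPS:
        rows = pd.concat([obs[obs["status_group"] == group], shared])
        # group-specific observation wins over the shared value for the
        # same country/date/indicator; code and flag travel together
        rows = rows.drop_duplicates(subset=["country_code", "date", "indicator"],
                                    keep="first")
        codes = rows.pivot(index=["country_code", "date"], columns="indicator",
                           values="code")
        flags = rows.pivot(index=["country_code", "date"], columns="indicator",
                           values="flag")
        for m in members:
            if m not in codes:
                codes[m] = np.nan
                flags[m] = np.nan
        codes = codes[members]
        flags = flags[members]

        nan_mask = codes.isna()
        if nan_mask.to_numpy().any():
            if strict:
                i, j = np.argwhere(nan_mask.to_numpy())[0]
                cc, date = codes.index[i]
                raise ValueError(
                    f"{cc}/{pd.Timestamp(date).date()}: member indicator "
                    f"{members[j]} has no observation (strict mode)"
                )
            logger.warning(
                "%s/%s: %d country-days averaged over incomplete members",
                index_name, group, int(nan_mask.any(axis=1).sum()),
            )

        scores = _subindex_matrix(codes, flags, codebook, members)
        with np.errstate(invalid="ignore"):
            values = np.nanmean(scores, axis=1) if not strict else np.mean(scores, axis=1)
        frame = pd.Series(values, index=codes.index).unstack(level=0)
        for cc in frame.columns:
            s = frame[cc].dropna()
            s.index = pd.DatetimeIndex(s.index)
            s = s.sort_index()
            out[(cc, group)] = IndexSeries(
                country_code=cc,
                index_name=index_name,
                status_group=group,
                values=s,
                country_name=str(names.get(cc, "")),
            )
    return out
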