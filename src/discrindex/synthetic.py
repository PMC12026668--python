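"""Synthetic policy panels with injected, known discrimination episodes.

A :class:`CountryProfile` describes one country's policy history as a
per-indicator baseline (constant or step function) applied to everyone,
plus :class:`EpisodeSpec` periods during which the non-vaccinated group is
subjected to extra ordinal steps on chosen differentiated indicators
(clamped at each indicator's maximum code) while the vaccinated group
keeps the baseline. This emulates the structure of real differentiated
policy panels — ordinal codes, scope flags, vaccinated / non-vaccinated
variants, pre-computed index columns, ISO alpha-3 join keys — without any
epidemiological content (no cases, no coverage).

Because every profile is a closed-form description, the expected composite
index and discrimination values are computable directly
(:func:`expected_index`, :func:`expected_discrimination`) without going
through the panel representation, giving the test suite an exact oracle
for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .codebook import Codebook, default_codebook
from .discrimination import study_window
from .index_engine import (
    NON_VACCINATED,
    SHARED,
    VACCINATED,
    subindex,
)
from .oxcgrt_io import OBS_COLUMNS, CountryRegion, observations_to_wide

__all__ = [
    "EpisodeSpec",
    "CountryProfile",
    "generate_panel",
    "generate_wide_panel",
    "published_indices",
    "expected_index",
    "expected_series",
    "expected_discrimination",
    "recovery_report",
    "default_profiles",
    "default_regions",
    "random_profiles",
    "jitter_onsets",
    "profiles_from_yaml",
]


@dataclass(frozen=True)
class EpisodeSpec:
    """A period of extra restrictions applied to the non-vaccinated group.

    ``deltas`` maps differentiated indicator ids to non-negative extra
    ordinal steps (clamped at the indicator's max code); ``flag`` is the
    geographic-scope flag recorded for the non-vaccinated variants during
    the episode.
    """

    start: str
    end: str
    deltas: dict
    flag: int = 1

    def __post_init__(self):
        if pd.Timestamp(self.start) > pd.Timestamp(self.end):
            raise ValueError(f"episode start {self.start} after end {self.end}")
        if any(d < 0 for d in self.deltas.values()):
            raise ValueError("episode deltas must be non-negative")
        if self.flag not in (0, 1):
            raise ValueError(f"episode flag must be 0 or 1, got {self.flag!r}")


@dataclass(frozen=True)
class CountryProfile:
    """Deterministic policy history for one synthetic country.

    ``baseline`` maps indicator id to either a constant code or a list of
    ``(date, code)`` steps (the code holds from that date onward; before
    the first step the code is 0). Unlisted indicators are 0 throughout.
    ``baseline_flags`` overrides the default nationwide flag (1) per
    indicator.
    """

    country_code: str
    country_name: str
    continent: str = ""
    sub_region: str = ""
    baseline: dict = field(default_factory=dict)
    baseline_flags: dict = field(default_factory=dict)
    episodes: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "episodes", tuple(self.episodes))

    def validate(self, codebook: Codebook) -> None:
        for iid, value in self.baseline.items():
            if iid not in codebook:
                raise ValueError(f"{self.country_code}: unknown indicator {iid!r}")
            spec = codebook[iid]
            codes = [value] if np.isscalar(value) else [c for _, c in value]
            for c in codes:
                if not (0 <= int(c) <= spec.max_code):
                    raise ValueError(
                        f"{self.country_code}/{iid}: baseline code {c} outside "
                        f"0..{spec.max_code}"
                    )
        for iid in self.baseline_flags:
            if iid not in codebook or not codebook[iid].has_flag:
                raise ValueError(
                    f"{self.country_code}: baseline flag for non-flagged "
                    f"indicator {iid!r}"
                )
        for ep in self.episodes:
            for iid in ep.deltas:
                if iid not in codebook or not codebook[iid].differentiated:
                    raise ValueError(
                        f"{self.country_code}: episode targets non-"
                        f"differentiated indicator {iid!r}"
                    )


def _baseline_codes(profile: CountryProfile, iid: str,
                    window: pd.DatetimeIndex) -> np.ndarray:
    """Daily baseline code array for one indicator over *window*."""
    value = profile.baseline.get(iid, 0)
    out = np.zeros(len(window), dtype=int)
    if np.isscalar(value):
        out[:] = int(value)
        return out
    for start, code in sorted(value, key=lambda t: pd.Timestamp(t[0])):
        out[window >= pd.Timestamp(start)] = int(code)
    return out


def _episode_arrays(profile: CountryProfile, iid: str, max_code: int,
                    base: np.ndarray, window: pd.DatetimeIndex):
    """(active mask, NV codes, NV flags) for one differentiated indicator."""
    active = np.zeros(len(window), dtype=bool)
    delta = np.zeros(len(window), dtype=int)
    flag = np.ones(len(window), dtype=int)
    for ep in profile.episodes:
        if iid not in ep.deltas:
            continue
        mask = (window >= pd.Timestamp(ep.start)) & (window <= pd.Timestamp(ep.end))
        active |= mask
        delta[mask] += int(ep.deltas[iid])
        flag[mask] = ep.flag
    nv = np.minimum(base + delta, max_code)
    return active, nv, flag


def generate_panel(
    profiles,
    window: pd.DatetimeIndex | None = None,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Expand profiles into tidy observations (schema of
    :data:`discrindex.oxcgrt_io.OBS_COLUMNS`).

    Every indicator gets a shared observation on every day (panels are
    complete: all indicators start at 0). During episodes, the targeted
    indicators additionally get a non-vaccinated variant (baseline plus
    delta, clamped) and a vaccinated variant (baseline).
    """
    if window is None:
        window = study_window()
    if codebook is None:
        codebook = default_codebook()
    frames = []
    for profile in profiles:
        profile.validate(codebook)
        n = len(window)
        for spec in codebook:
            base = _baseline_codes(profile, spec.id, window)
            base_flag = int(profile.baseline_flags.get(spec.id, 1))
            shared_flag = np.where(
                (base > 0) & spec.has_flag, float(base_flag), np.nan
            )
            frames.append(pd.DataFrame({
                "country_code": profile.country_code,
                "country_name": profile.country_name,
                "date": window,
                "indicator": spec.id,
                "status_group": SHARED,
                "code": base,
                "flag": shared_flag,
            }))
            if not spec.differentiated:
                continue
            active, nv, ep_flag = _episode_arrays(
                profile, spec.id, spec.max_code, base, window
            )
            if not active.any():
                continue
            idx = np.flatnonzero(active)
            nv_flag = np.where(
                (nv[idx] > 0) & spec.has_flag, ep_flag[idx].astype(float), np.nan
            )
            v_flag = np.where(
                (base[idx] > 0) & spec.has_flag, float(base_flag), np.nan
            )
            frames.append(pd.DataFrame({
                "country_code": profile.country_code,
                "country_name": profile.country_name,
                "date": window[idx],
                "indicator": spec.id,
                "status_group": NON_VACCINATED,
                "code": nv[idx],
                "flag": nv_flag,
            }))
            frames.append(pd.DataFrame({
                "country_code": profile.country_code,
                "country_name": profile.country_name,
                "date": window[idx],
                "indicator": spec.id,
                "status_group": VACCINATED,
                "code": base[idx],
                "flag": v_flag,
            }))
    if not frames:
        return pd.DataFrame(columns=OBS_COLUMNS)
    return pd.concat(frames, ignore_index=True)[OBS_COLUMNS]


def expected_index(
    profile: CountryProfile,
    date,
    index_name: str,
    status_group: str,
    codebook: Codebook | None = None,
) -> float:
    """Closed-form composite index value for one profile, day and group.

    Evaluates the sub-index formula directly from the profile's codes and
    flags, bypassing the panel representation entirely.
    """
    if codebook is None:
        codebook = default_codebook()
    date = pd.Timestamp(date)
    window = pd.DatetimeIndex([date])
    members = codebook.members(index_name)
    scores = np.empty(len(members), dtype=float)
    for k, iid in enumerate(members):
        spec = codebook[iid]
        base = int(_baseline_codes(profile, iid, window)[0])
        code, flag_value = base, int(profile.baseline_flags.get(iid, 1))
        if spec.differentiated and status_group == NON_VACCINATED:
            active, nv, ep_flag = _episode_arrays(
                profile, iid, spec.max_code, np.array([base]), window
            )
            if active[0]:
                code, flag_value = int(nv[0]), int(ep_flag[0])
        scores[k] = subindex(code, flag_value if spec.has_flag else None, spec)
    return float(np.mean(scores))


def expected_series(
    profile: CountryProfile,
    window: pd.DatetimeIndex,
    index_name: str,
    status_group: str,
    codebook: Codebook | None = None,
) -> pd.Series:
    """Daily oracle values of :func:`expected_index` over *window*."""
    if codebook is None:
        codebook = default_codebook()
    members = codebook.members(index_name)
    scores = np.empty((len(window), len(members)), dtype=float)
    for k, iid in enumerate(members):
        spec = codebook[iid]
        base = _baseline_codes(profile, iid, window)
        flag = np.full(len(window), int(profile.baseline_flags.get(iid, 1)))
        code = base.copy()
        if spec.differentiated and status_group == NON_VACCINATED:
            active, nv, ep_flag = _episode_arrays(
                profile, iid, spec.max_code, base, window
            )
            code = np.where(active, nv, base)
            flag = np.where(active, ep_flag, flag)
        col = np.array([
            subindex(int(c), int(f) if spec.has_flag else None, spec)
            for c, f in zip(code, flag)
        ])
        scores[:, k] = col
    return pd.Series(np.mean(scores, axis=1), index=window)


def expected_discrimination(
    profile: CountryProfile,
    window: pd.DatetimeIndex,
    index_basis: str = "CHI",
    codebook: Codebook | None = None,
) -> pd.Series:
    """Oracle daily discrimination values (non-vaccinated minus vaccinated)."""
    nv = expected_series(profile, window, index_basis, NON_VACCINATED, codebook)
    v = expected_series(profile, window, index_basis, VACCINATED, codebook)
    return nv - v


def published_indices(
    profiles,
    window: pd.DatetimeIndex | None = None,
    codebook: Codebook | None = None,
    *,
    decimals: int = 2,
) -> pd.DataFrame:
    """Pre-computed index columns (both bases, both groups) as a panel
    publisher would ship them, rounded to *decimals*."""
    if window is None:
        window = study_window()
    if codebook is None:
        codebook = default_codebook()
    frames = []
    for profile in profiles:
        for index_name in ("CHI", "STRINGENCY"):
            for group in (NON_VACCINATED, VACCINATED):
                s = expected_series(profile, window, index_name, group, codebook)
                frames.append(pd.DataFrame({
                    "country_code": profile.country_code,
                    "country_name": profile.country_name,
                    "date": window,
                    "index_name": index_name,
                    "status_group": group,
                    "value": s.to_numpy().round(decimals),
                }))
    if not frames:
        return pd.DataFrame(columns=["country_code", "country_name", "date",
                                     "index_name", "status_group", "value"])
    return pd.concat(frames, ignore_index=True)


def generate_wide_panel(
    profiles,
    window: pd.DatetimeIndex | None = None,
    codebook: Codebook | None = None,
    *,
    include_indices: bool = True,
) -> pd.DataFrame:
    """Wide CSV-shaped panel in the v1 dialect, optionally with the
    pre-computed index columns."""
    if codebook is None:
        codebook = default_codebook()
    obs = generate_panel(profiles, window, codebook)
    pub = published_indices(profiles, window, codebook) if include_indices else None
    return observations_to_wide(obs, codebook, published=pub)


def recovery_report(
    profiles,
    summaries,
    *,
    index_basis: str = "CHI",
    window: pd.DatetimeIndex | None = None,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Compare injected (oracle) vs pipeline-recovered mean/max discrimination.

    ``summaries`` is the pipeline's per-country summary frame (or list of
    :class:`~discrindex.aggregation.CountrySummary`). Absolute errors are
    zero for a correct pipeline on deterministic profiles.
    """
    from .aggregation import summaries_to_frame

    if window is None:
        window = study_window()
    df = summaries_to_frame(summaries).set_index("country_code")
    rows = []
    for profile in profiles:
        oracle = expected_discrimination(profile, window, index_basis, codebook)
        injected_mean = float(oracle.mean())
        injected_max = float(oracle.max())
        got_mean = float(df.loc[profile.country_code, "mean_D"])
        got_max = float(df.loc[profile.country_code, "max_D"])
        rows.append({
            "country_code": profile.country_code,
            "injected_mean_D": injected_mean,
            "recovered_mean_D": got_mean,
            "mean_abs_error": abs(got_mean - injected_mean),
            "injected_max_D": injected_max,
            "recovered_max_D": got_max,
            "max_abs_error": abs(got_max - injected_max),
        })
    return pd.DataFrame(rows, columns=[
        "country_code", "injected_mean_D", "recovered_mean_D", "mean_abs_error",
        "injected_max_D", "recovered_max_D", "max_abs_error",
    ])


# ---------------------------------------------------------------------------
# Built-in deterministic fixture set (synthetic stand-ins; real ISO codes are
# reused only as join keys, the histories are invented).
# ---------------------------------------------------------------------------

def default_profiles() -> list:
    """Twelve-plus synthetic countries across five continents.

    Onsets range from January 2021 to March 2022 and magnitudes from mild
    single-indicator episodes to broad multi-indicator regimes, mimicking
    the early-adopter / late-adopter structure of real differentiated
    policy timelines; two countries never differentiate (one with a very
    high baseline index, one very low) so the zero-discrimination
    partition is non-trivial. Fully deterministic.
    """
    p = CountryProfile
    e = EpisodeSpec
    return [
        p("AZE", "Azerbaijan", "Asia", "Western Asia",
          baseline={"C1": 2, "C2": 2, "C3": 1, "C4": 3, "C6": 1, "C8": 3,
                    "H1": 2, "H2": 2, "H3": 1, "H6": 3,
                    "H7": [("2021-02-01", 2), ("2021-07-01", 4)], "H8": 2},
          episodes=[e("2021-10-01", "2022-12-31",
                      {"C1": 1, "C2": 1, "C3": 1, "C4": 1, "C5": 1,
                       "C6": 1, "C7": 1, "H6": 1})]),
        p("PAK", "Pakistan", "Asia", "Southern Asia",
          baseline={"C1": 1, "C2": 1, "C3": 1, "C4": 2, "C8": 2,
                    "H1": 2, "H2": 1, "H6": 2,
                    "H7": [("2021-03-01", 1), ("2021-09-01", 3)], "H8": 1},
          episodes=[e("2022-03-15", "2022-12-31",
                      {"C1": 2, "C2": 2, "C3": 1, "C4": 3, "C5": 1,
                       "C6": 1, "C7": 1, "C8": 2, "H6": 2, "H8": 1})]),
        p("RWA", "Rwanda", "Africa", "Eastern Africa",
          baseline={"C1": 1, "C2": 1, "C4": 2, "C6": 1, "C8": 2,
                    "H1": 2, "H2": 1, "H6": 2, "H7": [("2021-05-01", 2)],
                    "H8": 1},
          episodes=[e("2021-12-20", "2022-12-31",
                      {"C2": 2, "C3": 2, "C4": 2, "C5": 1, "C6": 1, "C7": 1})]),
        p("FRA", "France", "Europe", "Western Europe",
          baseline={"C1": 1, "C2": 1, "C3": 1, "C4": 2, "C6": 1, "C8": 2,
                    "H1": 2, "H2": 3, "H3": 1, "H6": 3,
                    "H7": [("2021-01-10", 2), ("2021-06-15", 5)], "H8": 2},
          episodes=[e("2021-08-01", "2022-03-13",
                      {"C1": 1, "C2": 1, "C3": 1, "C4": 2, "C5": 1,
                       "C6": 1, "C7": 1, "H6": 1})]),
        p("EST", "Estonia", "Europe", "Northern Europe",
          baseline={"C1": 1, "C3": 1, "C4": 1, "C8": 2, "H1": 2, "H2": 2,
                    "H3": 2, "H6": 2, "H7": [("2021-01-05", 1),
                                             ("2021-05-01", 4)]},
          episodes=[e("2021-01-15", "2021-12-31", {"C3": 1, "C5": 1}),
                    e("2022-01-01", "2022-02-15", {"C3": 1})]),
        p("DEU", "Germany", "Europe", "Western Europe",
          baseline={"C1": 2, "C2": 2, "C3": 1, "C4": 2, "C6": 1, "C8": 3,
                    "H1": 2, "H2": 2, "H3": 1, "H6": 3,
                    "H7": [("2021-01-20", 2), ("2021-06-07", 5)], "H8": 2},
          # regionally targeted episode (flag 0) exercises the 0.5 deduction
          episodes=[e("2021-08-23", "2022-04-03",
                      {"C2": 1, "C3": 1, "C4": 1, "H6": 1}, flag=0)]),
        p("USA", "United States", "North America", "Northern America",
          baseline={"C1": 1, "C2": 1, "C4": 1, "C8": 2, "H1": 2, "H2": 2,
                    "H3": 1, "H6": 2, "H7": [("2021-01-01", 3),
                                             ("2021-04-19", 5)], "H8": 1},
          baseline_flags={"C1": 0, "C4": 0},
          episodes=[e("2021-04-05", "2022-03-31", {"C2": 1, "C4": 1})]),
        p("BLZ", "Belize", "North America", "Central America",
          baseline={"C4": 1, "C8": 2, "H1": 1, "H6": 2,
                    "H7": [("2021-03-15", 2)]},
          episodes=[e("2021-04-12", "2021-10-31", {"C4": 1})]),
        p("ARG", "Argentina", "South America", "South America",
          baseline={"C1": 1, "C2": 1, "C3": 1, "C4": 2, "C6": 1, "C8": 3,
                    "H1": 2, "H2": 2, "H6": 3, "H7": [("2021-02-01", 2),
                                                      ("2021-08-01", 4)],
                    "H8": 1},
          episodes=[e("2021-09-01", "2022-04-30",
                      {"C3": 1, "C4": 2, "C5": 1, "C7": 1})]),
        p("FJI", "Fiji", "Oceania", "Melanesia",
          baseline={"C1": 1, "C3": 1, "C4": 2, "C8": 3, "H1": 2, "H6": 2,
                    "H7": [("2021-04-01", 2)]},
          episodes=[e("2021-11-15", "2022-09-30",
                      {"C1": 2, "C2": 2, "C3": 1, "C4": 2, "C5": 1, "C7": 1})]),
        p("MAR", "Morocco", "Africa", "Northern Africa",
          baseline={"C1": 1, "C2": 1, "C3": 1, "C4": 2, "C6": 1, "C8": 3,
                    "H1": 2, "H2": 1, "H6": 3, "H7": [("2021-02-10", 3)],
                    "H8": 1},
          baseline_flags={"C6": 0},
          episodes=[e("2021-08-10", "2022-06-30",
                      {"C2": 1, "C4": 2, "C5": 1, "C6": 1, "C7": 1, "H6": 1})]),
        p("DZA", "Algeria", "Africa", "Northern Africa",
          baseline={"C1": 1, "C3": 1, "C4": 1, "C8": 2, "H1": 1, "H6": 2,
                    "H7": [("2021-03-01", 2)]},
          episodes=[e("2022-01-10", "2022-07-31", {"C3": 1, "C4": 1, "C5": 1})]),
        p("CHN", "China", "Asia", "Eastern Asia",
          baseline={"C1": 3, "C2": 2, "C3": 2, "C4": 4, "C5": 1, "C6": 2,
                    "C7": 2, "C8": 4, "H1": 2, "H2": 3, "H3": 2, "H6": 3,
                    "H7": [("2021-01-01", 3), ("2021-06-01", 5)], "H8": 3}),
        p("TZA", "Tanzania", "Africa", "Eastern Africa",
          baseline={"C8": 1, "H1": 1, "H7": [("2021-08-01", 1)]}),
    ]


def default_regions() -> list:
    """Region lookup rows covering the default fixture countries, plus a
    few codes absent from the panel (as a real lookup list would have)."""
    rows = [
        ("Azerbaijan", "AZE", "Western Asia", "Asia"),
        ("Pakistan", "PAK", "Southern Asia", "Asia"),
        ("Rwanda", "RWA", "Eastern Africa", "Africa"),
        ("France", "FRA", "Western Europe", "Europe"),
        ("Estonia", "EST", "Northern Europe", "Europe"),
        ("Germany", "DEU", "Western Europe", "Europe"),
        ("United States", "USA", "Northern America", "North America"),
        ("Belize", "BLZ", "Central America", "North America"),
        ("Argentina", "ARG", "South America", "South America"),
        ("Fiji", "FJI", "Melanesia", "Oceania"),
        ("Morocco", "MAR", "Northern Africa", "Africa"),
        ("Algeria", "DZA", "Northern Africa", "Africa"),
        ("China", "CHN", "Eastern Asia", "Asia"),
        ("Tanzania", "TZA", "Eastern Africa", "Africa"),
        ("Japan", "JPN", "Eastern Asia", "Asia"),
        ("Brazil", "BRA", "South America", "South America"),
        ("Kenya", "KEN", "Eastern Africa", "Africa"),
    ]
    return [CountryRegion(n, c, s, k) for n, c, s, k in rows]


def random_profiles(
    n: int,
    rng: np.random.Generator,
    codebook: Codebook | None = None,
    *,
    window: pd.DatetimeIndex | None = None,
    max_episodes: int = 2,
) -> list:
    """Randomized profiles for property fuzzing (valid by construction)."""
    if codebook is None:
        codebook = default_codebook()
    if window is None:
        window = study_window()
    diff_ids = codebook.differentiated_ids()
    out = []
    for i in range(n):
        baseline = {
            spec.id: int(rng.integers(0, spec.max_code + 1))
            for spec in codebook if rng.random() < 0.7
        }
        flags = {
            spec.id: int(rng.integers(0, 2))
            for spec in codebook if spec.has_flag and rng.random() < 0.3
        }
        episodes = []
        for _ in range(int(rng.integers(0, max_episodes + 1))):
            a, b = sorted(rng.integers(0, len(window), size=2))
            targets = rng.choice(
                diff_ids, size=int(rng.integers(1, len(diff_ids) + 1)),
                replace=False,
            )
            episodes.append(EpisodeSpec(
                start=str(window[a].date()),
                end=str(window[b].date()),
                deltas={t: int(rng.integers(0, 4)) for t in targets},
                flag=int(rng.integers(0, 2)),
            ))
        out.append(CountryProfile(
            country_code=f"S{i:02d}X"[:3].ljust(3, "Z"),
            country_name=f"Synthetic {i}",
            baseline=baseline,
            baseline_flags=flags,
            episodes=episodes,
        ))
    return out


def jitter_onsets(profiles, rng: np.random.Generator, max_days: int = 14) -> list:
    """Shift every episode's start by a uniform random offset in
    [-max_days, max_days] (end dates fixed; starts never pass ends)."""
    out = []
    for profile in profiles:
        episodes = []
        for ep in profile.episodes:
            shift = int(rng.integers(-max_days, max_days + 1))
            start = pd.Timestamp(ep.start) + pd.Timedelta(days=shift)
            start = min(start, pd.Timestamp(ep.end))
            episodes.append(EpisodeSpec(str(start.date()), ep.end,
                                        dict(ep.deltas), ep.flag))
        out.append(CountryProfile(
            country_code=profile.country_code,
            country_name=profile.country_name,
            continent=profile.continent,
            sub_region=profile.sub_region,
            baseline=dict(profile.baseline),
            baseline_flags=dict(profile.baseline_flags),
            episodes=episodes,
            seed=profile.seed,
        ))
    return out


def profiles_from_yaml(path) -> list:
    """Load profile definitions from a YAML/JSON config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = []
    for row in data["profiles"]:
        episodes = [
            EpisodeSpec(ep["start"], ep["end"], dict(ep["deltas"]),
                        int(ep.get("flag", 1)))
            for ep in row.get("episodes", ())
        ]
        baseline = {
            k: (v if np.isscalar(v) else [(s, int(c)) for s, c in v])
            for k, v in row.get("baseline", {}).items()
        }
        out.append(CountryProfile(
            country_code=row["country_code"],
            country_name=row.get("country_name", row["country_code"]),
            continent=row.get("continent", ""),
            sub_region=row.get("sub_region", ""),
            baseline=baseline,
            baseline_flags=dict(row.get("baseline_flags", {})),
            episodes=episodes,
            seed=row.get("seed"),
        ))
    return out
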