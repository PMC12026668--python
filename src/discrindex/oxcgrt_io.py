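"""Read and write policy-tracker panels and the countries-by-continent list.

The wide "v1 national" dialect has one row per country-day. Indicator
columns carry a status-variant infix between the indicator id and the
label: ``C1E_School closing`` (everyone / shared), ``C1NV_School closing``
(non-vaccinated), ``C1V_School closing`` (vaccinated); non-differentiated
indicators use the bare id (``H1_Public information campaigns``). Each
flagged variant has a ``_Flag`` companion (``C1E_Flag`` ...). Dates are
8-digit ``YYYYMMDD`` integers. Pre-computed composite index columns such
as ``ContainmentHealthIndex_NonVaccinated`` are captured separately when
present.

All column-name knowledge is isolated in :class:`PanelDialect`, so an
alternate archive layout only needs a different dialect instance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import Codebook, CHI, STRINGENCY
from .index_engine import NON_VACCINATED, SHARED, VACCINATED

__all__ = [
    "OBS_COLUMNS",
    "CONTINENTS",
    "PanelDialect",
    "V1_DIALECT",
    "CountryRegion",
    "read_policy_panel",
    "observations_to_wide",
    "read_country_regions",
    "join_regions",
    "write_tidy",
    "read_tidy",
]

logger = logging.getLogger(__name__)

#: tidy observation schema used throughout the package
OBS_COLUMNS = [
    "country_code", "country_name", "date", "indicator", "status_group",
    "code", "flag",
]

CONTINENTS = ("Africa", "Asia", "Europe", "North America", "Oceania",
              "South America")

_VARIANT_TO_GROUP = {None: SHARED, "E": SHARED, "NV": NON_VACCINATED,
                     "V": VACCINATED}
_GROUP_TO_VARIANT = {SHARED: "E", NON_VACCINATED: "NV", VACCINATED: "V"}


@dataclass(frozen=True)
class PanelDialect:
    """Column-name conventions of one wide panel layout."""

    country_code: str = "CountryCode"
    country_name: str = "CountryName"
    date: str = "Date"
    date_format: str = "%Y%m%d"
    #: regex with groups ``id`` (indicator), ``variant`` and ``rest``
    indicator_pattern: str = r"^(?P<id>[A-Z]\d{1,2})(?P<variant>NV|V|E)?_(?P<rest>.+)$"
    flag_label: str = "Flag"
    #: published composite index column -> (index_name, status_group)
    index_columns: dict = field(default_factory=lambda: {
        "ContainmentHealthIndex_NonVaccinated": (CHI, NON_VACCINATED),
        "ContainmentHealthIndex_Vaccinated": (CHI, VACCINATED),
        "StringencyIndex_NonVaccinated": (STRINGENCY, NON_VACCINATED),
        "StringencyIndex_Vaccinated": (STRINGENCY, VACCINATED),
    })

    def indicator_column(self, spec, status_group: str) -> str:
        """Wide column name for an indicator's code in one status group."""
        infix = _GROUP_TO_VARIANT[status_group] if spec.differentiated else ""
        return f"{spec.id}{infix}_{spec.label}"

    def flag_column(self, spec, status_group: str) -> str:
        infix = _GROUP_TO_VARIANT[status_group] if spec.differentiated else ""
        return f"{spec.id}{infix}_{self.flag_label}"

    def index_column(self, index_name: str, status_group: str) -> str:
        for col, (name, group) in self.index_columns.items():
            if (name, group) == (index_name, status_group):
                return col
        raise KeyError((index_name, status_group))


V1_DIALECT = PanelDialect()


@dataclass(frozen=True)
class CountryRegion:
    """One row of the countries-by-continent lookup."""

    country_name: str
    iso3: str
    sub_region: str
    continent: str


def _classify_columns(columns, codebook: Codebook, dialect: PanelDialect):
    """Map wide columns to (indicator id, status_group, is_flag) triples."""
    pat = re.compile(dialect.indicator_pattern)
    mapping = {}
    for col in columns:
        m = pat.match(col)
        if not m:
            continue
        iid, variant, rest = m.group("id"), m.group("variant"), m.group("rest")
        if iid not in codebook:
            logger.warning("skipping unknown indicator column %r", col)
            continue
        spec = codebook[iid]
        group = _VARIANT_TO_GROUP[variant]
        if group != SHARED and not spec.differentiated:
            logger.warning(
                "skipping column %r: %s is not a differentiated indicator",
                col, iid,
            )
            continue
        is_flag = rest == dialect.flag_label
        if is_flag and not spec.has_flag:
            logger.warning("skipping column %r: %s has no flag variable", col, iid)
            continue
        mapping[col] = (iid, group, is_flag)
    return mapping


def read_policy_panel(path, codebook: Codebook, *, dialect: PanelDialect = V1_DIALECT):
    """Parse a wide panel CSV into tidy observations + published index values.

    Returns
    -------
    observations : DataFrame
        Columns :data:`OBS_COLUMNS`; one row per country/date/indicator/
        status group with a recorded code. Missing cells stay absent
        (never imputed to zero here).
    published : DataFrame
        Columns ``country_code, country_name, date, index_name,
        status_group, value`` for the pre-computed index columns present
        in the file (may be empty).

    Raises
    ------
    ValueError
        On unparseable dates or codes outside the codebook's ordinal range
        (the error names the country, date and indicator).
    """
    wide = pd.read_csv(path, dtype={dialect.date: str}, low_memory=False)
    for col in (dialect.country_code, dialect.country_name, dialect.date):
        if col not in wide.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    try:
        dates = pd.to_datetime(wide[dialect.date], format=dialect.date_format)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date value ({exc})") from exc

    mapping = _classify_columns(wide.columns, codebook, dialect)
    base = pd.DataFrame({
        "country_code": wide[dialect.country_code],
        "country_name": wide[dialect.country_name],
        "date": dates,
    })

    code_cols = {k: v for k, v in mapping.items() if not v[2]}
    flag_cols = {(iid, grp): col for col, (iid, grp, is_flag) in mapping.items()
                 if is_flag}

    frames = []
    for col, (iid, group, _) in code_cols.items():
        codes = pd.to_numeric(wide[col], errors="coerce")
        present = codes.notna()
        if not present.any():
            continue
        spec = codebook[iid]
        vals = codes[present]
        bad = (vals < 0) | (vals > spec.max_code) | (vals != np.floor(vals))
        if bad.any():
            i = bad[bad].index[0]
            raise ValueError(
                f"{base.loc[i, 'country_code']}/{base.loc[i, 'date'].date()}/"
                f"{iid}: code {vals[i]} outside ordinal range 0..{spec.max_code}"
            )
        chunk = base[present].copy()
        chunk["indicator"] = iid
        chunk["status_group"] = group
        chunk["code"] = vals.astype(int)
        fcol = flag_cols.get((iid, group))
        chunk["flag"] = (
            pd.to_numeric(wide.loc[present, fcol], errors="coerce")
            if fcol is not None else np.nan
        )
        frames.append(chunk)

    obs = (
        pd.concat(frames, ignore_index=True)[OBS_COLUMNS]
        if frames else pd.DataFrame(columns=OBS_COLUMNS)
    )

    pub_frames = []
    for col, (index_name, group) in dialect.index_columns.items():
        if col not in wide.columns:
            continue
        vals = pd.to_numeric(wide[col], errors="coerce")
        present = vals.notna()
        if ((vals[present] < 0) | (vals[present] > 100)).any():
            raise ValueError(f"{path}: {col} contains values outside [0, 100]")
        chunk = base[present].copy()
        chunk["index_name"] = index_name
        chunk["status_group"] = group
        chunk["value"] = vals[present]
        pub_frames.append(chunk)
    published = (
        pd.concat(pub_frames, ignore_index=True)
        if pub_frames
        else pd.DataFrame(columns=["country_code", "country_name", "date",
                                   "index_name", "status_group", "value"])
    )
    return obs, published


def observations_to_wide(
    obs: pd.DataFrame,
    codebook: Codebook,
    *,
    dialect: PanelDialect = V1_DIALECT,
    published: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inverse of :func:`read_policy_panel`: tidy observations -> wide rows.

    Cells without an observation are left blank. ``published`` optionally
    supplies pre-computed index columns (same schema as the reader's
    second return value).
    """
    base = (
        obs[["country_code", "country_name", "date"]]
        .drop_duplicates()
        .sort_values(["country_code", "date"])
        .reset_index(drop=True)
    )
    wide = pd.DataFrame({
        dialect.country_code: base["country_code"],
        dialect.country_name: base["country_name"],
        dialect.date: base["date"].dt.strftime(dialect.date_format),
    })
    key = pd.MultiIndex.from_frame(base[["country_code", "date"]])
    for spec in codebook:
        groups = (
            (SHARED, NON_VACCINATED, VACCINATED) if spec.differentiated
            else (SHARED,)
        )
        for group in groups:
            sub = obs[(obs["indicator"] == spec.id) & (obs["status_group"] == group)]
            sub = sub.set_index(["country_code", "date"])
            wide[dialect.indicator_column(spec, group)] = (
                sub["code"].reindex(key).to_numpy()
            )
            if spec.has_flag:
                wide[dialect.flag_column(spec, group)] = (
                    sub["flag"].reindex(key).to_numpy()
                )
    if published is not None and len(published):
        pub = published.set_index(["country_code", "date"])
        for col, (index_name, group) in dialect.index_columns.items():
            sel = pub[(pub["index_name"] == index_name)
                      & (pub["status_group"] == group)]
            if len(sel):
                wide[col] = sel["value"].reindex(key).to_numpy()
    return wide


_REGION_FIELD_ALIASES = {
    "country_name": ("country_name", "country or area", "country", "name"),
    "iso3": ("iso3", "iso-alpha3 code", "iso_alpha3", "iso3 code", "country code"),
    "sub_region": ("sub_region", "sub-region", "subregion", "region 1", "region"),
    "continent": ("continent",),
}


def read_country_regions(path) -> list:
    """Read the countries-by-continent list (name, ISO alpha-3, sub-region,
    continent); returns a list of :class:`CountryRegion`."""
    df = pd.read_csv(path)
    norm = {str(c).strip().lower(): c for c in df.columns}
    cols = {}
    for fieldname, aliases in _REGION_FIELD_ALIASES.items():
        for alias in aliases:
            if alias in norm:
                cols[fieldname] = norm[alias]
                break
        else:
            raise ValueError(f"{path}: missing required field {fieldname!r}")
    if df.empty:
        logger.warning("%s: empty countries-by-continent list", path)
        return []
    iso = df[cols["iso3"]].astype(str).str.strip()
    if iso.duplicated().any():
        dupes = sorted(iso[iso.duplicated()].unique())
        raise ValueError(f"{path}: duplicate iso3 codes {dupes}")
    if df[list(cols.values())].isna().any().any():
        i = df[list(cols.values())].isna().any(axis=1).idxmax()
        raise ValueError(f"{path}: missing field value in row {i}")
    regions = [
        CountryRegion(
            country_name=str(r[cols["country_name"]]).strip(),
            iso3=str(r[cols["iso3"]]).strip(),
            sub_region=str(r[cols["sub_region"]]).strip(),
            continent=str(r[cols["continent"]]).strip(),
        )
        for _, r in df.iterrows()
    ]
    odd = sorted({r.continent for r in regions} - set(CONTINENTS))
    if odd:
        logger.warning("continents outside the usual six retained: %s", odd)
    return regions


def join_regions(panel_countries, regions):
    """Match panel country codes against the region list by ISO alpha-3.

    Returns ``(mapping, unmatched)`` where ``mapping`` is a dict
    iso3 -> :class:`CountryRegion` restricted to matched panel countries
    and ``unmatched`` lists panel codes absent from the region list
    (reported, never dropped silently).
    """
    by_iso = {r.iso3: r for r in regions}
    mapping, unmatched = {}, []
    for code in sorted(set(panel_countries)):
        if code in by_iso:
            mapping[code] = by_iso[code]
        else:
            unmatched.append(code)
    if unmatched:
        logger.warning(
            "%d panel countries not in the region list: %s",
            len(unmatched), unmatched,
        )
    return mapping, unmatched


def write_tidy(frame: pd.DataFrame, path, *, decimals: int = 2) -> None:
    """Write a long-format table; numeric values rounded to *decimals*."""
    out = frame.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)


def read_tidy(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df
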