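"""Equal-interval classification, timeline tables, and pipeline orchestration.

Classification partitions a fixed value domain into k equal-width classes
for choropleth legends (defaults: five classes over [0, 20] for
per-country averages and [0, 40] for maxima). Intervals are
left-open/right-closed except the first class, which includes the lower
domain bound; a value outside the domain is a hard error, never clipped.

:func:`run_pipeline` wires the whole analysis together — panel input (real
files or synthetic profiles), index computation (published columns or
recomputed from indicator codes), the daily discrimination series,
per-country summaries, rankings, the zero-discrimination partition,
regional grouping, classified map tables and timeline tables — into one
deterministic bundle with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (
    association,
    group_by_region,
    rank_countries,
    summaries_to_frame,
    summarize_country,
    zero_partition,
)
from .codebook import CHI, Codebook, default_codebook
from .discrimination import (
    DiscriminationSeries,
    discrimination_series,
    study_window,
)
from .index_engine import (
    IndexSeries,
    NON_VACCINATED,
    VACCINATED,
    build_index_series,
)
from .oxcgrt_io import join_regions, read_country_regions, read_policy_panel, write_tidy

__all__ = [
    "ClassifiedValue",
    "equal_interval_classes",
    "timeline_table",
    "PipelineConfig",
    "PipelineBundle",
    "run_pipeline",
    "write_bundle",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifiedValue:
    country_code: str
    value: float
    class_index: int
    lower: float
    upper: float


def equal_interval_classes(
    values, k: int = 5, domain_min: float = 0.0, domain_max: float = 40.0
) -> pd.DataFrame:
    """Assign each value to one of *k* equal-width classes over the domain.

    ``values`` maps country code to value (dict or Series). Class ``c``
    covers ``(domain_min + (c-1)*w, domain_min + c*w]`` with
    ``w = (domain_max - domain_min) / k``; the first class also includes
    ``domain_min`` itself. Values outside the domain raise ``ValueError``.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 classes, got {k}")
    if not domain_max > domain_min:
        raise ValueError(f"empty domain [{domain_min}, {domain_max}]")
    series = pd.Series(values, dtype=float)
    width = (domain_max - domain_min) / k
    arr = series.to_numpy()
    out_of_domain = (arr < domain_min) | (arr > domain_max)
    if out_of_domain.any():
        code = series.index[np.argmax(out_of_domain)]
        raise ValueError(
            f"{code}: value {series[code]} outside classification domain "
            f"[{domain_min}, {domain_max}]"
        )
    # right-closed intervals: a value exactly on a boundary belongs below;
    # the ratio is rounded to guard against float noise on exact boundaries
    ratio = np.round((arr - domain_min) / width, 9)
    classes = np.clip(np.ceil(ratio).astype(int), 1, k)
    return pd.DataFrame({
        "country_code": series.index,
        "value": arr,
        "class_index": classes,
        "lower": domain_min + (classes - 1) * width,
        "upper": domain_min + classes * width,
    }).reset_index(drop=True)


def timeline_table(
    series_collection,
    regions,
    *,
    level: str | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Long table (date, country, value, region labels) for line charts.

    ``series_collection`` is an iterable of :class:`DiscriminationSeries`
    (or :class:`IndexSeries`); ``regions`` maps country code to
    :class:`CountryRegion`. With ``level`` ("continent" or "sub_region")
    and ``label``, rows are restricted to that group; an unknown label is
    a hard error listing the valid ones, while a valid label with no data
    yields an empty table with a warning.
    """
    if (level is None) != (label is None):
        raise ValueError("level and label must be supplied together")
    if level is not None and level not in ("continent", "sub_region"):
        raise ValueError(f"level must be 'continent' or 'sub_region', got {level!r}")
    if level is not None:
        valid = sorted({getattr(r, level) for r in regions.values()})
        if label not in valid:
            raise ValueError(
                f"unknown {level} {label!r}; valid labels: {valid}"
            )
    frames = []
    for s in series_collection:
        region = regions.get(s.country_code)
        continent = region.continent if region else ""
        sub_region = region.sub_region if region else ""
        if level is not None and (
            (level == "continent" and continent != label)
            or (level == "sub_region" and sub_region != label)
        ):
            continue
        frames.append(pd.DataFrame({
            "date": s.values.index,
            "country_code": s.country_code,
            "country_name": s.country_name,
            "value": s.values.to_numpy(),
            "continent": continent,
            "sub_region": sub_region,
        }))
    if not frames:
        if level is not None:
            logger.warning("no series in %s %r; empty timeline", level, label)
        return pd.DataFrame(columns=["date", "country_code", "country_name",
                                     "value", "continent", "sub_region"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["country_code", "date"]).reset_index(drop=True)


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on.

    Exactly one input source: either the wide panel files
    (``input_2021`` + ``input_2022`` + ``regions_path``) or a synthetic
    profile list (``profiles``). ``source`` selects whether composite
    indices are taken from the panel's published columns or recomputed
    from the indicator codes.
    """

    input_2021: str | None = None
    input_2022: str | None = None
    regions_path: str | None = None
    profiles: list | None = None
    basis: str = CHI
    source: str = "recomputed"  # or "published"
    classes: int = 5
    mean_domain: tuple = (0.0, 20.0)
    max_domain: tuple = (0.0, 40.0)
    top_n: int = 10
    strict: bool = True
    codebook: Codebook = field(default_factory=default_codebook)
    seed: int | None = None


@dataclass
class PipelineBundle:
    """All artifacts of one pipeline run."""

    summaries: pd.DataFrame
    ranking_mean: pd.DataFrame
    ranking_max: pd.DataFrame
    partition: object
    by_continent: pd.DataFrame
    by_sub_region: pd.DataFrame
    classified_mean: pd.DataFrame
    classified_max: pd.DataFrame
    timeline: pd.DataFrame
    discrimination: dict
    index_series: dict
    associations: dict
    unmatched: list
    recovery: pd.DataFrame | None
    manifest: dict


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _series_from_published(published: pd.DataFrame, basis: str) -> dict:
    out = {}
    sel = published[published["index_name"] == basis]
    for (cc, group), sub in sel.groupby(["country_code", "status_group"]):
        sub = sub.sort_values("date")
        values = pd.Series(sub["value"].to_numpy(dtype=float),
                           index=pd.DatetimeIndex(sub["date"]))
        out[(cc, group)] = IndexSeries(
            country_code=cc,
            index_name=basis,
            status_group=group,
            values=values,
            country_name=str(sub["country_name"].iloc[0]),
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute the full analysis described by *config*."""
    cb = config.codebook
    window = study_window()
    manifest_inputs = {}
    recovery = None

    if config.profiles is not None:
        from .synthetic import (
            default_regions,
            generate_panel,
            published_indices,
            recovery_report,
        )

        obs = generate_panel(config.profiles, window, cb)
        published = (
            published_indices(config.profiles, window, cb)
            if config.source == "published" else pd.DataFrame()
        )
        regions_list = default_regions()
        manifest_inputs["profiles"] = hashlib.sha256(
            repr(config.profiles).encode()
        ).hexdigest()
    else:
        if not (config.input_2021 and config.input_2022 and config.regions_path):
            raise ValueError(
                "config needs either synthetic profiles or the two annual "
                "panel files plus the regions list"
            )
        frames, pubs = [], []
        for path in (config.input_2021, config.input_2022):
            o, p = read_policy_panel(path, cb)
            frames.append(o)
            pubs.append(p)
            manifest_inputs[str(path)] = _file_sha256(path)
        obs = pd.concat(frames, ignore_index=True)
        dup = obs.duplicated(
            subset=["country_code", "date", "indicator", "status_group"]
        )
        if dup.any():
            row = obs[dup].iloc[0]
            raise ValueError(
                f"annual files overlap at {row['country_code']}/"
                f"{row['date'].date()}"
            )
        published = pd.concat(pubs, ignore_index=True)
        regions_list = read_country_regions(config.regions_path)
        manifest_inputs[str(config.regions_path)] = _file_sha256(config.regions_path)

    if config.source == "published":
        if published.empty:
            raise ValueError("source='published' but no published index columns")
        series = _series_from_published(published, config.basis)
    elif config.source == "recomputed":
        series = build_index_series(obs, cb, config.basis, strict=config.strict)
    else:
        raise ValueError(f"unknown source {config.source!r}")

    countries = sorted({cc for cc, _ in series})
    regions_map, unmatched = join_regions(countries, regions_list)

    disc, summaries = {}, []
    for cc in countries:
        try:
            d = discrimination_series(series[(cc, NON_VACCINATED)],
                                      series[(cc, VACCINATED)])
        except KeyError as exc:
            raise ValueError(f"stage discrimination: {cc}: missing series "
                             f"{exc}") from exc
        disc[cc] = d
        summaries.append(summarize_country(
            d, series[(cc, NON_VACCINATED)], regions_map.get(cc),
            window=window, permissive=not config.strict,
        ))
    sdf = summaries_to_frame(summaries)

    if config.profiles is not None:
        recovery = recovery_report(
            config.profiles, sdf, index_basis=config.basis, window=window,
            codebook=cb,
        )

    associations = {
        "mean_vs_max": association(sdf, "mean_D", "max_D"),
        "mean_vs_chi": association(sdf, "mean_D", "mean_CHI"),
    }
    bundle = PipelineBundle(
        summaries=sdf,
        ranking_mean=rank_countries(sdf, "mean_D", config.top_n),
        ranking_max=rank_countries(sdf, "max_D", config.top_n),
        partition=zero_partition(sdf),
        by_continent=group_by_region(sdf, "continent"),
        by_sub_region=group_by_region(sdf, "sub_region"),
        classified_mean=equal_interval_classes(
            sdf.set_index("country_code")["mean_D"], config.classes,
            *config.mean_domain,
        ),
        classified_max=equal_interval_classes(
            sdf.set_index("country_code")["max_D"], config.classes,
            *config.max_domain,
        ),
        timeline=timeline_table(disc.values(), regions_map),
        discrimination=disc,
        index_series=series,
        associations=associations,
        unmatched=unmatched,
        recovery=recovery,
        manifest={
            "package_version": __version__,
            "codebook_version": cb.version(),
            "basis": config.basis,
            "source": config.source,
            "classes": config.classes,
            "mean_domain": list(config.mean_domain),
            "max_domain": list(config.max_domain),
            "strict": config.strict,
            "seed": config.seed,
            "window": [str(window[0].date()), str(window[-1].date())],
            "inputs": manifest_inputs,
        },
    )
    return bundle


def write_bundle(bundle: PipelineBundle, out_dir) -> None:
    """Write every bundle table as CSV plus the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tidy(bundle.summaries, out / "summaries.csv")
    write_tidy(bundle.ranking_mean, out / "ranking_mean.csv")
    write_tidy(bundle.ranking_max, out / "ranking_max.csv")
    write_tidy(bundle.by_continent, out / "by_continent.csv")
    write_tidy(bundle.by_sub_region, out / "by_sub_region.csv")
    write_tidy(bundle.classified_mean, out / "classified_mean.csv")
    write_tidy(bundle.classified_max, out / "classified_max.csv")
    write_tidy(bundle.timeline, out / "timeline.csv")
    if bundle.recovery is not None:
        write_tidy(bundle.recovery, out / "recovery_report.csv")
    tidy = pd.concat(
        [
            pd.DataFrame({
                "country_code": d.country_code,
                "country_name": d.country_name,
                "date": d.values.index,
                "discrimination_index": d.values.to_numpy(),
            })
            for d in bundle.discrimination.values()
        ],
        ignore_index=True,
    ) if bundle.discrimination else pd.DataFrame(
        columns=["country_code", "country_name", "date", "discrimination_index"]
    )
    write_tidy(tidy, out / "discrimination_daily.csv")
    manifest = dict(bundle.manifest)
    manifest["associations"] = {
        k: v._asdict() for k, v in bundle.associations.items()
    }
    manifest["unmatched"] = bundle.unmatched
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
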