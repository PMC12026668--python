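import json
import logging

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import discrindex as dx
from discrindex import synthetic as syn
from discrindex.cli import main as cli_main
from discrindex.reporting import (
    equal_interval_classes,
    run_pipeline,
    timeline_table,
    write_bundle,
)


class TestEqualIntervalClasses:
    @pytest.mark.parametrize("value,domain,expected", [
        (10.58, (0, 20), 3),   # middle class of the average-discrimination map
        (0.0, (0, 20), 1),     # lower domain bound belongs to the first class
        (38.69, (0, 40), 5),   # top class of the maximum-discrimination map
        (20.0, (0, 20), 5),
        (8.0, (0, 20), 2),     # exact boundary is right-closed
        (8.0001, (0, 20), 3),
        (40.0, (0, 40), 5),
        (32.0, (0, 40), 4),
    ])
    def test_class_assignment(self, value, domain, expected):
        out = equal_interval_classes({"AAA": value}, 5, *domain)
        assert out.loc[0, "class_index"] == expected

    def test_bounds_partition_domain(self):
        out = equal_interval_classes(
            {f"C{i:02d}": v for i, v in enumerate(np.linspace(0, 40, 21))},
            5, 0, 40)
        widths = out["upper"] - out["lower"]
        np.testing.assert_allclose(widths, 8.0)
        assert ((out["value"] > out["lower"]) | (out["class_index"] == 1)).all()
        assert (out["value"] <= out["upper"]).all()

    def test_classification_idempotent(self):
        values = {"AAA": 3.2, "BBB": 17.5, "CCC": 9.99}
        a = equal_interval_classes(values, 5, 0, 20)
        b = equal_interval_classes(values, 5, 0, 20)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_domain_is_hard_error(self):
        with pytest.raises(ValueError, match="outside"):
            equal_interval_classes({"AAA": 45.0}, 5, 0, 40)
        with pytest.raises(ValueError, match="outside"):
            equal_interval_classes({"AAA": -0.1}, 5, 0, 40)

    def test_degenerate_arguments(self):
        with pytest.raises(ValueError, match="k"):
            equal_interval_classes({"AAA": 1.0}, 1, 0, 40)
        with pytest.raises(ValueError, match="domain"):
            equal_interval_classes({"AAA": 1.0}, 5, 10, 10)


class TestTimelineTable:
    def test_unfiltered_has_all_countries(self, bundle, profiles):
        table = bundle.timeline
        assert table["country_code"].nunique() == len(profiles)
        assert list(table.columns[:4]) == ["date", "country_code",
                                           "country_name", "value"]

    def test_sorted_by_country_then_date(self, bundle):
        table = bundle.timeline
        key = list(zip(table["country_code"], table["date"]))
        assert key == sorted(key)

    def test_continent_filter(self, bundle, regions_map):
        table = timeline_table(bundle.discrimination.values(), regions_map,
                               level="continent", label="Africa")
        assert set(table["continent"]) == {"Africa"}
        assert set(table["country_code"]) == {"RWA", "MAR", "DZA", "TZA"}

    def test_sub_region_filter(self, bundle, regions_map):
        table = timeline_table(bundle.discrimination.values(), regions_map,
                               level="sub_region", label="Western Asia")
        assert set(table["country_code"]) == {"AZE"}

    def test_unknown_label_lists_valid(self, bundle, regions_map):
        with pytest.raises(ValueError, match="Atlantis.*Africa"):
            timeline_table(bundle.discrimination.values(), regions_map,
                           level="continent", label="Atlantis")

    def test_valid_label_without_data_warns_empty(self, bundle, regions_map,
                                                  caplog):
        # JPN exists in the lookup but has no series in the panel
        with caplog.at_level(logging.WARNING, logger="discrindex.reporting"):
            table = timeline_table(
                bundle.discrimination.values(), regions_map,
                level="sub_region", label="Eastern Asia")
        sub = table[table["country_code"] == "JPN"]
        assert sub.empty


class TestPipeline:
    def test_bundle_recovery_is_exact(self, bundle):
        assert bundle.recovery["mean_abs_error"].max() == 0.0
        assert bundle.recovery["max_abs_error"].max() == 0.0

    def test_manifest_determinism(self, profiles, bundle, tmp_path):
        again = run_pipeline(dx.PipelineConfig(profiles=profiles))
        assert again.manifest == bundle.manifest
        pd.testing.assert_frame_equal(again.summaries, bundle.summaries)
        out = tmp_path / "bundle"
        write_bundle(bundle, out)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["codebook_version"] == bundle.manifest["codebook_version"]
        for name in ("summaries", "ranking_mean", "ranking_max", "timeline",
                     "classified_mean", "classified_max", "recovery_report",
                     "discrimination_daily"):
            assert (out / f"{name}.csv").exists()

    def test_stringency_basis_runs_higher(self, profiles, bundle):
        """With differentiation concentrated in the C indicators, the
        9-member Stringency basis yields higher discrimination values than
        the 14-member containment-and-health basis."""
        stringent = run_pipeline(
            dx.PipelineConfig(profiles=profiles, basis="STRINGENCY",
                              mean_domain=(0.0, 40.0),
                              max_domain=(0.0, 60.0)))
        a = stringent.summaries.set_index("country_code")["mean_D"]
        b = bundle.summaries.set_index("country_code")["mean_D"]
        discriminating = b[b > 0].index
        assert (a[discriminating] > b[discriminating]).mean() > 0.7
        assert a.mean() > b.mean()

    def test_published_and_recomputed_paths_agree(self, profiles, bundle):
        """Recomputed indices match the panel's published columns to within
        their 2-decimal rounding."""
        published = run_pipeline(
            dx.PipelineConfig(profiles=profiles, source="published"))
        diff = (
            published.summaries.set_index("country_code")[["mean_D", "max_D"]]
            - bundle.summaries.set_index("country_code")[["mean_D", "max_D"]]
        ).abs()
        assert diff.to_numpy().max() < 0.01

    def test_zero_partition_on_fixture(self, bundle):
        part = bundle.partition
        assert set(part.zero["country_code"]) == {"CHN", "TZA"}
        assert len(part.zero) + len(part.nonzero) == len(bundle.summaries)

    def test_unmatched_countries_surface(self, profiles):
        extra = profiles + [syn.CountryProfile("XKX", "Kosovo", "Europe",
                                               "Southern Europe")]
        out = run_pipeline(dx.PipelineConfig(profiles=extra))
        assert out.unmatched == ["XKX"]
        assert "XKX" in set(out.summaries["country_code"])

    def test_incomplete_config_rejected(self):
        with pytest.raises(ValueError, match="config"):
            run_pipeline(dx.PipelineConfig())

    def test_file_based_pipeline(self, profiles, codebook, tmp_path):
        """Annual wide files + regions list through the reader path, stacked
        across the year boundary."""
        sub = profiles[:3]
        y21 = pd.date_range("2021-01-01", "2021-12-31")
        y22 = pd.date_range("2022-01-01", "2022-12-31")
        syn.generate_wide_panel(sub, y21, codebook).to_csv(
            tmp_path / "panel_2021.csv", index=False)
        syn.generate_wide_panel(sub, y22, codebook).to_csv(
            tmp_path / "panel_2022.csv", index=False)
        pd.DataFrame(
            [r.__dict__ for r in syn.default_regions()]
        ).rename(columns={"iso3": "iso3"}).to_csv(
            tmp_path / "regions.csv", index=False)
        out = run_pipeline(dx.PipelineConfig(
            input_2021=str(tmp_path / "panel_2021.csv"),
            input_2022=str(tmp_path / "panel_2022.csv"),
            regions_path=str(tmp_path / "regions.csv"),
        ))
        assert len(out.summaries) == 3
        ref = run_pipeline(dx.PipelineConfig(profiles=sub))
        pd.testing.assert_frame_equal(
            out.summaries.sort_values("country_code").reset_index(drop=True),
            ref.summaries.sort_values("country_code").reset_index(drop=True))


class TestCli:
    def test_compute_and_rank(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "bundle"
        result = runner.invoke(cli_main, ["compute", "--synthetic",
                                          "--out-dir", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "summaries.csv").exists()
        result = runner.invoke(cli_main, ["rank", "--synthetic",
                                          "--by", "max_D", "--top", "3"])
        assert result.exit_code == 0, result.output
        assert "PAK" in result.output

    def test_simulate_roundtrip(self, tmp_path, codebook):
        runner = CliRunner()
        out = tmp_path / "sim"
        result = runner.invoke(cli_main, ["simulate", "--out-dir", str(out),
                                          "--seed", "3", "--jitter-days", "5"])
        assert result.exit_code == 0, result.output
        obs, pub = dx.read_policy_panel(out / "synthetic_panel_v1.csv", codebook)
        assert not obs.empty and not pub.empty

    def test_partition_command(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["partition", "--synthetic"])
        assert result.exit_code == 0, result.output
        assert "zero-discrimination countries: 2" in result.output
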