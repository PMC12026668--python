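import logging

import numpy as np
import pandas as pd
import pytest

import discrindex as dx
from discrindex import synthetic as syn
from discrindex.oxcgrt_io import (
    CountryRegion,
    join_regions,
    observations_to_wide,
    read_country_regions,
    read_policy_panel,
    read_tidy,
    write_tidy,
)


@pytest.fixture(scope="module")
def small_panel(codebook):
    """Two-country, 20-day panel with one differentiation episode."""
    window = pd.date_range("2021-03-01", periods=20)
    profiles = [
        syn.CountryProfile(
            "AAA", "Alphaland", baseline={"C1": 3, "H2": 1},
            episodes=[syn.EpisodeSpec("2021-03-05", "2021-03-10",
                                      {"C1": 0, "C4": 2}, flag=1)]),
        syn.CountryProfile("BBB", "Betaland"),
    ]
    obs = syn.generate_panel(profiles, window, codebook)
    wide = observations_to_wide(
        obs, codebook, published=syn.published_indices(profiles, window, codebook))
    return profiles, window, obs, wide


class TestReadPolicyPanel:
    def test_field_mapping(self, small_panel, codebook, tmp_path):
        _, _, _, wide = small_panel
        path = tmp_path / "panel.csv"
        wide.to_csv(path, index=False)
        obs, published = read_policy_panel(path, codebook)
        row = obs[(obs.country_code == "AAA") & (obs.indicator == "C4")
                  & (obs.status_group == dx.NON_VACCINATED)].iloc[0]
        assert row["code"] == 2 and row["flag"] == 1
        assert not published.empty
        assert published["value"].between(0, 100).all()

    def test_all_zero_country_parses_to_zero_codes(self, small_panel, codebook,
                                                   tmp_path):
        _, _, _, wide = small_panel
        path = tmp_path / "panel.csv"
        wide.to_csv(path, index=False)
        obs, _ = read_policy_panel(path, codebook)
        bbb = obs[obs.country_code == "BBB"]
        assert (bbb["code"] == 0).all()
        assert bbb["flag"].isna().all()

    def test_out_of_range_code_is_hard_error(self, small_panel, codebook,
                                             tmp_path):
        _, _, _, wide = small_panel
        bad = wide.copy()
        bad.loc[0, "C1E_School closing"] = 5
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="C1.*0..3"):
            read_policy_panel(path, codebook)

    def test_unknown_indicator_column_warned_and_skipped(
            self, small_panel, codebook, tmp_path, caplog):
        _, _, obs, wide = small_panel
        extra = wide.copy()
        extra["E1_Income support"] = 1
        path = tmp_path / "extra.csv"
        extra.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING, logger="discrindex.oxcgrt_io"):
            obs2, _ = read_policy_panel(path, codebook)
        assert "E1" in caplog.text
        assert set(obs2["indicator"]) <= set(codebook.ids)
        assert len(obs2) == len(obs)

    def test_unparseable_date_is_hard_error(self, small_panel, codebook,
                                            tmp_path):
        _, _, _, wide = small_panel
        bad = wide.copy()
        bad.loc[0, "Date"] = "not-a-date"
        path = tmp_path / "baddate.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="date"):
            read_policy_panel(path, codebook)

    def test_roundtrip_is_lossless(self, small_panel, codebook, tmp_path):
        """panel -> model -> wide write -> re-read preserves codes and flags."""
        _, _, obs, wide = small_panel
        path = tmp_path / "roundtrip.csv"
        wide.to_csv(path, index=False)
        obs2, _ = read_policy_panel(path, codebook)
        key = ["country_code", "date", "indicator", "status_group"]
        a = obs.sort_values(key).reset_index(drop=True)
        b = obs2.sort_values(key).reset_index(drop=True)
        assert len(a) == len(b)
        assert (a["code"].to_numpy() == b["code"].to_numpy()).all()
        np.testing.assert_array_equal(
            a["flag"].to_numpy(dtype=float), b["flag"].to_numpy(dtype=float))

    def test_reader_never_invents_observations(self, small_panel, codebook,
                                               tmp_path):
        _, _, _, wide = small_panel
        path = tmp_path / "count.csv"
        wide.to_csv(path, index=False)
        obs, _ = read_policy_panel(path, codebook)
        n_value_columns = sum(
            1 for c in wide.columns
            if c[:2] in codebook and not c.endswith("Flag"))
        assert len(obs) <= len(wide) * n_value_columns


class TestCountryRegions:
    def _write(self, tmp_path, rows, header="country_name,iso3,sub_region,continent"):
        path = tmp_path / "regions.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_basic_row(self, tmp_path):
        path = self._write(tmp_path, ["Rwanda,RWA,Eastern Africa,Africa"])
        regions = read_country_regions(path)
        assert regions == [CountryRegion("Rwanda", "RWA", "Eastern Africa",
                                         "Africa")]

    def test_row_count_preserved(self, tmp_path):
        rows = [f"Country{i},A{i:02d},Sub,Africa" for i in range(40)]
        assert len(read_country_regions(self._write(tmp_path, rows))) == 40

    def test_statisticstimes_style_headers(self, tmp_path):
        path = self._write(
            tmp_path, ["France,FRA,Western Europe,Europe"],
            header="Country or Area,ISO-alpha3 Code,Region 1,Continent")
        assert read_country_regions(path)[0].iso3 == "FRA"

    def test_duplicate_iso3_rejected(self, tmp_path):
        path = self._write(tmp_path, ["A,AAA,S,Africa", "B,AAA,S,Africa"])
        with pytest.raises(ValueError, match="duplicate"):
            read_country_regions(path)

    def test_missing_field_rejected(self, tmp_path):
        path = self._write(tmp_path, ["A,AAA,S,Africa"],
                           header="country_name,iso3,sub_region,landmass")
        with pytest.raises(ValueError, match="continent"):
            read_country_regions(path)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = self._write(tmp_path, [])
        with caplog.at_level(logging.WARNING, logger="discrindex.oxcgrt_io"):
            assert read_country_regions(path) == []
        assert "empty" in caplog.text


class TestJoinRegions:
    REGIONS = [CountryRegion("France", "FRA", "Western Europe", "Europe"),
               CountryRegion("Kenya", "KEN", "Eastern Africa", "Africa")]

    def test_match_and_unmatched_reported(self):
        mapping, unmatched = join_regions(["FRA", "XKX"], self.REGIONS)
        assert mapping["FRA"].continent == "Europe"
        assert unmatched == ["XKX"]

    def test_no_silent_drops(self):
        panel = ["FRA", "KEN", "ZZZ"]
        mapping, unmatched = join_regions(panel, self.REGIONS)
        assert set(mapping) | set(unmatched) == set(panel)

    def test_superset_region_list(self):
        mapping, unmatched = join_regions(["KEN"], self.REGIONS)
        assert list(mapping) == ["KEN"] and unmatched == []


class TestTidyIO:
    def test_series_roundtrip_two_decimals(self, tmp_path):
        df = pd.DataFrame({
            "country_code": ["AAA"] * 3,
            "date": pd.date_range("2021-01-01", periods=3),
            "discrimination_index": [0.123456, 7.891, 10.0],
        })
        path = tmp_path / "tidy.csv"
        write_tidy(df, path)
        back = read_tidy(path)
        np.testing.assert_allclose(back["discrimination_index"],
                                   df["discrimination_index"].round(2))
        assert back["date"].equals(df["date"])

    def test_empty_frame_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_tidy(pd.DataFrame(columns=["country_code", "date", "value"]), path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["country_code,date,value"]

    def test_summary_rows(self, tmp_path, bundle):
        path = tmp_path / "summaries.csv"
        write_tidy(bundle.summaries.head(3), path)
        assert len(read_tidy(path)) == 3
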