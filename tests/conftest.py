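import pandas as pd
import pytest

import discrindex as dx
from discrindex import synthetic as syn


@pytest.fixture(scope="session")
def codebook():
    return dx.default_codebook()


@pytest.fixture(scope="session")
def window():
    return dx.study_window()


@pytest.fixture(scope="session")
def profiles():
    return syn.default_profiles()


@pytest.fixture(scope="session")
def bundle(profiles):
    """Full pipeline run on the deterministic fixture set (recomputed path)."""
    return dx.run_pipeline(dx.PipelineConfig(profiles=profiles))


@pytest.fixture(scope="session")
def regions_map():
    return {r.iso3: r for r in syn.default_regions()}


def make_index_series(values, *, country="TST", basis="CHI",
                      group=dx.NON_VACCINATED, start="2021-01-01"):
    """Small helper: wrap raw numbers in an IndexSeries on a daily axis."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    return dx.IndexSeries(
        country_code=country, index_name=basis, status_group=group,
        values=pd.Series(list(values), index=idx, dtype=float),
    )


@pytest.fixture
def series_factory():
    return make_index_series
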