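import pytest

import isopair as ip


@pytest.fixture(scope="session")
def catalog_events():
    return ip.load_catalog()


@pytest.fixture(scope="session")
def response_lists():
    return ip.load_gene_response_lists()


@pytest.fixture(scope="session")
def t5_table():
    return ip.load_tumour_normal_stats()


@pytest.fixture(scope="session")
def t6_table():
    return ip.load_gleason_corr_stats()


@pytest.fixture(scope="session")
def t7_table():
    return ip.load_stage_corr_stats()
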