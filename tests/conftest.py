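import pytest

from isoloss import (
    build_feature_report,
    call_all,
    character_map,
    make_fixture_fig2a,
    region_template,
)


@pytest.fixture(scope="session")
def template_ann():
    return region_template()


@pytest.fixture(scope="session")
def fig2a():
    return make_fixture_fig2a(seed=1)


@pytest.fixture(scope="session")
def fig2a_reports(fig2a):
    ref = fig2a.alignment.reference
    ann = fig2a.alignment.annotation
    return {
        row.species_id: build_feature_report(row, ref, ann)
        for row in fig2a.alignment.rows
    }


@pytest.fixture(scope="session")
def fig2a_calls(fig2a_reports):
    return call_all(list(fig2a_reports.values()))


@pytest.fixture(scope="session")
def fig2a_states(fig2a_calls):
    return character_map(fig2a_calls)
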