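import pytest

import symbiopoly as sp
from symbiopoly.fixtures import load_fixtures


@pytest.fixture(scope="session")
def gatb_amplicons():
    """Per-line gatB amplicon sets realising the published variant matrix."""
    return load_fixtures("gatB_table1_amplicons")


@pytest.fixture(scope="session")
def gatb_meta():
    return {m.clone_id: m for m in load_fixtures("gatB_table1_metadata")}


@pytest.fixture(scope="session")
def gatb_calls(gatb_amplicons, gatb_meta):
    calls = []
    for amp in gatb_amplicons.values():
        calls += sp.call_snps(amp, gatb_meta)
    return calls
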