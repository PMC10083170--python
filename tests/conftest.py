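import logging

import pytest

from lymphplex.records import SampleAlterationProfile

# silence off-panel warnings during bulk synthetic runs
logging.getLogger("lymphplex.ingest").setLevel(logging.ERROR)


def make_profile(genes=(), fbcl2=False, fbcl6=False, myc=False,
                 sample_id="s1") -> SampleAlterationProfile:
    return SampleAlterationProfile(
        sample_id=sample_id,
        mutated_genes=frozenset(genes),
        fbcl2=fbcl2,
        fbcl6=fbcl6,
        myc_rearranged=myc,
    )


@pytest.fixture()
def fixture_dir(tmp_path):
    from lymphplex.synth import make_fixtures

    return {"paths": make_fixtures(tmp_path), "dir": tmp_path}
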