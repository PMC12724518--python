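"""Shared fixtures: one small synthetic study reused across test modules.

Session scope keeps the simulation cost (a few seconds) paid once; tests
never mutate the fixtures.
"""

import pytest

from nmscan import caller
from nmscan.simulate import make_study, simulate_riboxi


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 2 x 10 kb contigs, 18 planted sites
    (10 constitutive incl. one tandem pair, 4 SNORD116, 4 SNORD113/114)."""
    return make_study(seed=1)


@pytest.fixture(scope="session")
def ct2_records(study):
    return simulate_riboxi(study.reference, study.truth, study.config, "CT2")


@pytest.fixture(scope="session")
def ct2_coverage(ct2_records):
    deduped = caller.dedupe_umis(caller.filter_records(ct2_records))
    return caller.end3_coverage(deduped)
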