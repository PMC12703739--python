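import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile("repro", database=None, derandomize=True, deadline=None)
settings.load_profile("repro")

from minimask import fixtures

SUITE_SEED = 11
SUITE_SIZE = 40


@pytest.fixture(scope="session")
def fixture_suite():
    """The 40-design synthetic suite with planted ground truth."""
    return [
        fixtures.make_bundle_fixture(spec, f"design_{i:03d}")
        for i, spec in enumerate(fixtures.random_fixture_specs(SUITE_SIZE, SUITE_SEED))
    ]


@pytest.fixture(scope="session")
def one_fixture():
    spec = fixtures.FixtureSpec(mask_length=20, target_coverage=0.75, seed=3)
    return fixtures.make_bundle_fixture(spec, "single")
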