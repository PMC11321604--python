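import numpy as np
import pytest

from rpcseg.synthetic import CohortSpec, default_scanner_profiles, generate_cohort


@pytest.fixture(scope="session")
def profiles():
    return default_scanner_profiles()


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory, profiles):
    """Small 2-scanner cohort on disk for I/O and orchestration tests."""
    root = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(
        cases=(("center_a", "philips", 2), ("center_d", "3dhistech", 2)),
        roi_size=128,
        rng_seed=7,
    )
    manifest = generate_cohort(spec, profiles, root)
    return root, manifest, spec
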