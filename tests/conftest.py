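import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isasync import synth
from isasync.preprocess import preprocess_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240927)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest cohort that clears the FIR edge margin at 8 Hz."""
    return synth.CohortSpec(
        n_expert=2,
        n_novice=2,
        n_channels=8,
        fs=8.0,
        duration=1800.0,
        n_sessions=1,
        bands=(0.05,),
        kappa_expert=4.0,
        kappa_novice=1.0,
        jitter_dwell=300.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return synth.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_entries(tiny_spec, tiny_cohort):
    """Preprocessed (no Laplacian) phase tensors grouped by participant."""
    by_pid = {}
    for rec, _ in tiny_cohort:
        eeg_pt, gsr_pt = preprocess_recording(
            rec, tiny_spec.bands, apply_csd=False, keep_bandpassed=True
        )
        entry = by_pid.setdefault(
            rec.participant.id, {"participant": rec.participant, "sessions": []}
        )
        entry["sessions"].append((eeg_pt, gsr_pt))
    return list(by_pid.values())
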