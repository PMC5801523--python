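import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swaybam as sb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_trial(
    acc: np.ndarray,
    fs: float = 50.0,
    subject_id: str = "S001",
    device: str = "waist",
    condition: int = 1,
    attempt: int = 1,
    **kwargs,
) -> sb.TrialRecording:
    """Uniformly sampled trial around a given (n, 3) acceleration array."""
    acc = np.asarray(acc, dtype=float)
    ts = (1000.0 / fs) * np.arange(acc.shape[0])
    return sb.TrialRecording(
        subject_id=subject_id,
        device=device,
        condition=condition,
        attempt=attempt,
        sample_rate_hz=fs,
        timestamps_ms=ts,
        acc_mg=acc,
        **kwargs,
    )


@pytest.fixture(scope="session")
def paper_study():
    """One default-configuration study at full scale (42 subjects × 6
    conditions × 2 attempts × 2 devices) plus its analysis report."""
    config = sb.SimulationConfig(seed=7)
    trials, manifest, truth = sb.simulate_study(config)
    report = sb.analyze_trials(trials, manifest)
    return config, trials, manifest, truth, report


@pytest.fixture(scope="session")
def tiny_study():
    """4-subject study for fast bookkeeping tests."""
    config = sb.SimulationConfig(n_subjects=4, seed=11)
    trials, manifest, truth = sb.simulate_study(config)
    return config, trials, manifest, truth
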