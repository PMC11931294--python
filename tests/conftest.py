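import numpy as np
import pandas as pd
import pytest

import hemoloco as hl


@pytest.fixture(scope="session")
def spectra() -> hl.ChromophoreSpectra:
    return hl.ChromophoreSpectra.default()


@pytest.fixture
def small_config() -> hl.SimConfig:
    """A short, small-frame, noise-free session for fast forward-model tests."""
    return hl.SimConfig(
        seed=7,
        duration_s=60.0,
        n_events=2,
        image_size=(24, 24),
        noise_sd=0.0,
        amplitude_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def default_study() -> hl.StudyResult:
    """The default seeded multi-session study, shared across tests (read-only)."""
    return hl.simulate_study(seed=0)


def make_epochs(data: np.ndarray, rate: float = 32.0, normalized: bool = True,
                units: str = "%") -> hl.EventEpochs:
    """Wrap a raw (events × 800) array as EventEpochs for metric tests."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return hl.EventEpochs(
        data=data,
        rate=rate,
        normalized=normalized,
        units=units,
        keys=pd.DataFrame({c: [f"x{i}" for i in range(data.shape[0])]
                           for c in ("animal_id", "session_id", "event_id", "vessel", "genotype")}),
    )
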