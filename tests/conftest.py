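import numpy as np
import pytest

from rgcestim.core import (
    AnalysisConfig,
    RecordingSession,
    SpikeTrain,
    StimulusProtocol,
    mea_channel_map,
)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def light_protocol():
    """2 s ON / 2 s OFF full-field alternation, 20 repeats."""
    return StimulusProtocol(
        protocol_id="light",
        kind="light",
        onsets=5.0 + 4.0 * np.arange(20),
        on_duration_s=2.0,
        off_duration_s=2.0,
        n_repeats=20,
    )


def make_electrical(amplitude=30.0, duration=2.0, n_pulses=50, start=3.0):
    return StimulusProtocol(
        protocol_id=f"estim_A{amplitude:g}uA_D{duration:g}ms",
        kind="electrical",
        onsets=start + 1.0 * np.arange(n_pulses),
        amplitude_uA=amplitude,
        phase_duration_ms=duration,
    )


@pytest.fixture
def electrical_protocol():
    return make_electrical()


def random_session(rng: np.random.Generator, n_cells: int = 3) -> RecordingSession:
    """Small random but valid session for round-trip tests."""
    channels = [c for c, _, _ in mea_channel_map()]
    trains = []
    for i in range(n_cells):
        n = int(rng.integers(0, 30))
        times = np.sort(rng.uniform(0.0, 100.0, n))
        times = np.unique(times)
        trains.append(
            SpikeTrain(
                cell_id=f"cell_{i:03d}",
                channel_id=int(rng.choice(channels)),
                unit_index=int(rng.integers(0, 3)),
                times=times,
            )
        )
    protocols = [
        StimulusProtocol(
            protocol_id="light",
            kind="light",
            onsets=np.arange(5.0, 85.0, 4.0),
            on_duration_s=2.0,
            off_duration_s=2.0,
            n_repeats=20,
        ),
        make_electrical(
            amplitude=float(rng.choice([10, 15, 20, 25, 30])),
            duration=float(rng.choice([0.5, 1.0, 2.0])),
            n_pulses=int(rng.integers(5, 20)),
            start=90.0,
        ),
    ]
    return RecordingSession(
        session_id="random",
        spike_trains=trains,
        protocols=protocols,
        group_label="normal" if rng.random() < 0.5 else "mnu_treated",
    )
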