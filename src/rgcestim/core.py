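"""Core data model for multi-electrode-array (MEA) retinal recordings.

All times are in seconds, float64, session-relative and 0-based.  Stimulus
pulse amplitudes are in microamps and per-phase durations in milliseconds,
the native units of the stimulation hardware; charge per phase is then
amplitude * duration in nanocoulombs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

log = logging.getLogger("rgcestim")

#: Channel id of the large internal reference electrode on the 60-channel
#: perforated MEA.  It is part of the channel map but never carries units.
REFERENCE_CHANNEL = 15

GROUP_LABELS = ("normal", "mnu_treated")
SEVERITY_LEVELS = ("normal", "non_severe", "severe")

#: Tested stimulus grid: 5 pulse amplitudes x 3 per-phase durations.
AMPLITUDE_GRID_UA = (10.0, 15.0, 20.0, 25.0, 30.0)
DURATION_GRID_MS = (0.5, 1.0, 2.0)


class SessionValidationError(ValueError):
    """A session, spike train or protocol violates its invariants."""


class ConfigurationError(ValueError):
    """The requested analysis cannot be run on the given inputs."""


def _as_times(values, what: str) -> np.ndarray:
    t = np.asarray(values, dtype=np.float64)
    if t.ndim != 1:
        raise SessionValidationError(f"{what} must be one-dimensional")
    if t.size and not np.all(np.isfinite(t)):
        raise SessionValidationError(f"non-finite value in {what}")
    return t


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit.

    Times are seconds from session start, strictly increasing and
    non-negative.
    """

    cell_id: str
    channel_id: int
    unit_index: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_times(self.times, f"spike times of {self.cell_id}")
        if self.times.size and self.times[0] < 0:
            raise SessionValidationError(
                f"negative spike time in cell {self.cell_id}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise SessionValidationError(
                f"spike times of cell {self.cell_id} not strictly increasing"
            )

    def count_between(self, t0: float, t1: float) -> int:
        """Number of spikes with t0 <= t < t1."""
        lo, hi = np.searchsorted(self.times, [t0, t1])
        return int(hi - lo)

    def counts_in_windows(self, starts: np.ndarray, width: float) -> np.ndarray:
        """Spike counts in half-open windows [s, s + width) for each start."""
        starts = np.asarray(starts, dtype=float)
        lo = np.searchsorted(self.times, starts)
        hi = np.searchsorted(self.times, starts + width)
        return (hi - lo).astype(np.int64)

    def __eq__(self, other) -> bool:  # value equality for round-trip tests
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.channel_id == other.channel_id
            and self.unit_index == other.unit_index
            and np.array_equal(self.times, other.times)
        )


@dataclass
class StimulusProtocol:
    """One stimulation block: a light alternation or an electrical pulse train.

    Electrical blocks are trains of identical symmetric cathodic-first
    biphasic pulses (one onset per pulse, nominally 1 s apart); light blocks
    are full-field ON/OFF alternations (one onset per ON phase).
    """

    protocol_id: str
    kind: str  # "light" | "electrical"
    onsets: np.ndarray
    amplitude_uA: float | None = None
    phase_duration_ms: float | None = None
    on_duration_s: float | None = None
    off_duration_s: float | None = None
    n_repeats: int | None = None
    polarity: str = "cathodic-first biphasic, symmetric"

    def __post_init__(self) -> None:
        if self.kind not in ("light", "electrical"):
            raise SessionValidationError(f"unknown protocol kind {self.kind!r}")
        self.onsets = _as_times(self.onsets, f"onsets of {self.protocol_id}")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise SessionValidationError(
                f"onsets of protocol {self.protocol_id} not strictly increasing"
            )
        if self.kind == "electrical":
            if self.amplitude_uA is None or self.phase_duration_ms is None:
                raise SessionValidationError(
                    f"electrical protocol {self.protocol_id} needs amplitude and"
                    " phase duration"
                )
            if self.amplitude_uA <= 0 or self.phase_duration_ms <= 0:
                raise SessionValidationError(
                    f"non-positive stimulus parameter in {self.protocol_id}"
                )
        else:
            if self.on_duration_s is None:
                self.on_duration_s = 2.0
            if self.off_duration_s is None:
                self.off_duration_s = 2.0
            if self.n_repeats is None:
                self.n_repeats = int(self.onsets.size)

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StimulusProtocol):
            return NotImplemented
        return (
            self.protocol_id == other.protocol_id
            and self.kind == other.kind
            and np.array_equal(self.onsets, other.onsets)
            and self.amplitude_uA == other.amplitude_uA
            and self.phase_duration_ms == other.phase_duration_ms
            and self.on_duration_s == other.on_duration_s
            and self.off_duration_s == other.off_duration_s
            and self.n_repeats == other.n_repeats
        )


def mea_channel_map() -> list[tuple[int, int, int]]:
    """Channel map of the 60-channel 8x8 perforated MEA.

    The 8x8 grid has no electrodes at its four corners, giving 60 channel
    positions; one of them (channel 15) is the large internal reference, so
    59 channels carry activity.  Returns (channel_id, grid_row, grid_col)
    with ids 1..60 in row-major order over occupied positions.
    """
    entries = []
    cid = 1
    for row in range(8):
        for col in range(8):
            if (row, col) in ((0, 0), (0, 7), (7, 0), (7, 7)):
                continue
            entries.append((cid, row, col))
            cid += 1
    return entries


@dataclass
class RecordingSession:
    """One retinal patch on the MEA: spike trains plus stimulation protocols."""

    session_id: str
    sampling_rate: float = 25000.0
    channel_map: list[tuple[int, int, int]] = field(default_factory=mea_channel_map)
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    protocols: list[StimulusProtocol] = field(default_factory=list)
    group_label: str = "normal"
    raw_traces: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SessionValidationError("sampling_rate must be positive")
        if self.group_label not in GROUP_LABELS:
            raise SessionValidationError(f"unknown group label {self.group_label!r}")
        known = {c for c, _, _ in self.channel_map}
        for train in self.spike_trains:
            if train.channel_id not in known:
                raise SessionValidationError(
                    f"cell {train.cell_id} on unknown channel {train.channel_id}"
                )

    # -- protocol access -------------------------------------------------
    def light_protocols(self) -> list[StimulusProtocol]:
        return [p for p in self.protocols if p.kind == "light"]

    def electrical_protocols(self) -> list[StimulusProtocol]:
        return [p for p in self.protocols if p.kind == "electrical"]

    def find_electrical(
        self, amplitude_uA: float, phase_duration_ms: float
    ) -> StimulusProtocol | None:
        for p in self.electrical_protocols():
            if (
                np.isclose(p.amplitude_uA, amplitude_uA)
                and np.isclose(p.phase_duration_ms, phase_duration_ms)
            ):
                return p
        return None

    def get_train(self, cell_id: str) -> SpikeTrain:
        for t in self.spike_trains:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecordingSession):
            return NotImplemented
        if (
            self.session_id != other.session_id
            or self.sampling_rate != other.sampling_rate
            or sorted(self.channel_map) != sorted(other.channel_map)
            or self.group_label != other.group_label
        ):
            return False
        if sorted(self.spike_trains, key=lambda t: t.cell_id) != sorted(
            other.spike_trains, key=lambda t: t.cell_id
        ):
            return False
        if sorted(self.protocols, key=lambda p: p.protocol_id) != sorted(
            other.protocols, key=lambda p: p.protocol_id
        ):
            return False
        a = self.raw_traces or {}
        b = other.raw_traces or {}
        if sorted(a) != sorted(b):
            return False
        return all(np.allclose(a[k], b[k], atol=1e-9) for k in a)


@dataclass
class AnalysisConfig:
    """Analysis constants.

    Defaults follow the published recording/analysis conventions: baseline
    from 20 pre-stimulus bins of 100 ms, evoked (indirect-response) window
    10-100 ms post pulse with the first 10 ms blanked for the stimulus
    artifact and direct responses, responsiveness at 1.5x baseline, 20 ms
    PSTH bins with a 99% confidence bound, spike detection at 4x noise SD
    after a 100 Hz high-pass, and a 30 um diameter stimulation electrode.
    """

    baseline_n_bins: int = 20
    baseline_bin_width: float = 0.1  # s
    evoked_window: tuple[float, float] = (0.010, 0.100)  # s post onset
    artifact_blank: tuple[float, float] = (0.0, 0.010)  # s post onset
    response_threshold_factor: float = 1.5
    psth_bin: float = 0.020  # s
    psth_confidence: float = 0.99
    psth_window: tuple[float, float] = (-0.5, 0.5)  # s around onset
    detect_sd_multiple: float = 4.0
    highpass_cutoff: float = 100.0  # Hz
    electrode_diameter_um: float = 30.0
    refractory_s: float = 0.001
    noise_method: str = "mad"  # robust default; "plain" = sample SD
    light_window_s: float = 0.5  # post-transition scoring window
    light_confidence: float = 0.99
    spearman_rho_min: float = 0.8  # "proportional" curve criterion
    max_trials: int | None = None  # None = use every onset present

    def __post_init__(self) -> None:
        if self.evoked_window[0] < self.artifact_blank[1]:
            raise ConfigurationError(
                "evoked window must start at or after the artifact blank ends"
            )
        for name in ("baseline_bin_width", "psth_bin", "light_window_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.baseline_n_bins <= 0:
            raise ConfigurationError("baseline_n_bins must be positive")
        if self.response_threshold_factor <= 1:
            raise ConfigurationError("response_threshold_factor must exceed 1")
        if self.noise_method not in ("plain", "mad"):
            raise ConfigurationError(f"unknown noise method {self.noise_method!r}")

    @property
    def baseline_span(self) -> float:
        """Total pre-stimulus baseline span in seconds (default 2 s)."""
        return self.baseline_n_bins * self.baseline_bin_width

    @property
    def evoked_width(self) -> float:
        return self.evoked_window[1] - self.evoked_window[0]

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            d[name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for name, f in cls.__dataclass_fields__.items():
            if name in d:
                v = d[name]
                kwargs[name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
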