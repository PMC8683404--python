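"""Electrically evoked response quantification.

Per cell and pulse train: spontaneous baseline from 20 pre-stimulus bins of
100 ms, evoked rate from the indirect-response window 10-100 ms after each
pulse (the first 10 ms is blanked to exclude the stimulus artifact and
direct responses), their ratio as the relative response, ES-responsiveness
at the strongest stimulus (30 uA / 2 ms) against the 1.5x-baseline level,
PSTHs with a 99% confidence bound, pulse-amplitude/-duration response
curves, and a well/poorly/un-modulated label based on curve monotonicity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, spearmanr

from .core import (
    AMPLITUDE_GRID_UA,
    DURATION_GRID_MS,
    AnalysisConfig,
    ConfigurationError,
    RecordingSession,
    SpikeTrain,
    StimulusProtocol,
)

log = logging.getLogger("rgcestim")


@dataclass
class TrialResponse:
    cell_id: str
    protocol_id: str
    amplitude_uA: float
    phase_duration_ms: float
    baseline_rate: float  # spikes/s
    evoked_rate: float  # spikes/s
    evoked_count_mean: float  # spikes per trial in the evoked window
    relative_response: float
    n_trials: int


@dataclass
class StimPSTH:
    cell_id: str
    protocol_id: str
    bin_edges: np.ndarray  # s relative to onset
    counts: np.ndarray  # spikes/bin averaged over trials
    confidence_level: float
    confidence_bound: float  # spikes/bin
    baseline_mean: float  # spikes/bin over pre-onset bins
    n_trials: int


@dataclass
class ResponseCurve:
    """Relative response along one modulated stimulus axis.

    mode "PAM": fixed per-phase duration (ms), x = amplitudes (uA).
    mode "PDM": fixed amplitude (uA), x = durations (ms).
    """

    cell_id: str
    mode: str  # PAM | PDM
    fixed_value: float
    x: np.ndarray
    y_relative: np.ndarray
    y_count: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_relative = np.asarray(self.y_relative, dtype=float)
        self.y_count = np.asarray(self.y_count, dtype=float)
        if self.x.size != self.y_relative.size:
            raise ValueError("x and y must have equal length")
        if self.x.size > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


@dataclass
class ModulationLabel:
    cell_id: str
    label: str  # well | poor | unmodulated
    rho: dict = field(default_factory=dict)  # (mode, fixed_value) -> Spearman rho
    es_responsive: bool = False


def _onsets(protocol: StimulusProtocol, config: AnalysisConfig) -> np.ndarray:
    on = protocol.onsets
    if config.max_trials is not None:
        on = on[: config.max_trials]
    return on


def baseline_rate(
    train: SpikeTrain, protocol: StimulusProtocol, config: AnalysisConfig | None = None
) -> float:
    """Spontaneous rate from the pre-stimulus baseline window (spikes/s).

    Counts spikes in the 20 x 100 ms bins immediately before the block's
    first pulse and divides by the 2 s total span.  Computed once per block:
    the 1 s inter-pulse spacing leaves no room for a 2 s window between
    pulses.
    """
    config = config or AnalysisConfig()
    span = config.baseline_span
    t0 = float(protocol.onsets[0]) - span
    if t0 < 0:
        raise ConfigurationError(
            f"protocol {protocol.protocol_id}: insufficient pre-stimulus span"
            f" ({protocol.onsets[0]:.3f} s < {span:.3f} s)"
        )
    return train.count_between(t0, float(protocol.onsets[0])) / span


def evoked_rate(
    train: SpikeTrain, protocol: StimulusProtocol, config: AnalysisConfig | None = None
) -> float:
    """Mean rate in the indirect window (onset+10 ms, onset+100 ms], spikes/s."""
    config = config or AnalysisConfig()
    return evoked_count_mean(train, protocol, config) / config.evoked_width


def evoked_count_mean(
    train: SpikeTrain, protocol: StimulusProtocol, config: AnalysisConfig | None = None
) -> float:
    """Mean spike count per trial in the evoked window."""
    config = config or AnalysisConfig()
    on = _onsets(protocol, config)
    if on.size == 0:
        raise ConfigurationError(f"protocol {protocol.protocol_id} has no onsets")
    lo, hi = config.evoked_window
    counts = train.counts_in_windows(on + lo, hi - lo)
    return float(counts.mean())


def relative_response(baseline: float, evoked: float) -> float:
    """Evoked / baseline rate ratio.

    Conventions: 0/0 -> 0 (silent cell); positive evoked over zero baseline
    -> +inf sentinel (unambiguously responsive).
    """
    if baseline < 0 or evoked < 0:
        raise ValueError("rates must be non-negative")
    if baseline == 0.0:
        return math.inf if evoked > 0 else 0.0
    return evoked / baseline


def trial_response(
    train: SpikeTrain, protocol: StimulusProtocol, config: AnalysisConfig | None = None
) -> TrialResponse:
    """Full per-cell, per-train response record."""
    config = config or AnalysisConfig()
    base = baseline_rate(train, protocol, config)
    count = evoked_count_mean(train, protocol, config)
    evoked = count / config.evoked_width
    return TrialResponse(
        cell_id=train.cell_id,
        protocol_id=protocol.protocol_id,
        amplitude_uA=float(protocol.amplitude_uA),
        phase_duration_ms=float(protocol.phase_duration_ms),
        baseline_rate=base,
        evoked_rate=evoked,
        evoked_count_mean=count,
        relative_response=relative_response(base, evoked),
        n_trials=int(_onsets(protocol, config).size),
    )


def is_es_responsive(
    train: SpikeTrain,
    session: RecordingSession,
    config: AnalysisConfig | None = None,
) -> bool:
    """Responsiveness to electrical stimulation at the strongest stimulus.

    True iff the relative response at 30 uA / 2 ms reaches the threshold
    factor (1.5x baseline).  A silent-baseline cell with any evoked spikes
    is responsive (the +inf sentinel).
    """
    config = config or AnalysisConfig()
    proto = session.find_electrical(max(AMPLITUDE_GRID_UA), max(DURATION_GRID_MS))
    if proto is None:
        raise ConfigurationError(
            "session lacks the strongest stimulus protocol (30 uA / 2 ms)"
        )
    r = trial_response(train, proto, config)
    return r.relative_response >= config.response_threshold_factor


def stim_psth(
    train: SpikeTrain, protocol: StimulusProtocol, config: AnalysisConfig | None = None
) -> StimPSTH:
    """Peri-stimulus time histogram with a 99% confidence bound.

    20 ms bins spanning -0.5 to +0.5 s around each pulse, counts averaged
    over trials.  The bound is the mean of the pre-onset (baseline) bins
    plus the two-sided normal 99% quantile times their SD, so a flat cell
    stays below it in ~99% of bins.
    """
    config = config or AnalysisConfig()
    on = _onsets(protocol, config)
    if on.size < 5:
        raise ConfigurationError("need at least 5 trials for a PSTH")
    lo, hi = config.psth_window
    edges = np.arange(lo, hi + 0.5 * config.psth_bin, config.psth_bin)
    rel = (train.times[None, :] - on[:, None]).ravel()
    rel = rel[(rel >= lo) & (rel < edges[-1])]
    counts, _ = np.histogram(rel, bins=edges)
    counts = counts / on.size
    n_base = int(np.searchsorted(edges[1:], 0.0, side="right"))  # bins ending <= 0
    baseline_bins = counts[:n_base]
    mean = float(baseline_bins.mean()) if baseline_bins.size else 0.0
    sd = float(baseline_bins.std(ddof=1)) if baseline_bins.size > 1 else 0.0
    z = norm.ppf(0.5 + config.psth_confidence / 2.0)
    return StimPSTH(
        cell_id=train.cell_id,
        protocol_id=protocol.protocol_id,
        bin_edges=edges,
        counts=counts,
        confidence_level=config.psth_confidence,
        confidence_bound=mean + z * sd,
        baseline_mean=mean,
        n_trials=int(on.size),
    )


def response_curves(
    train: SpikeTrain,
    session: RecordingSession,
    config: AnalysisConfig | None = None,
) -> list[ResponseCurve]:
    """All 8 modulation curves (3 PAM + 5 PDM) from the 15-stimulus grid.

    The same 15 (amplitude, duration) measurements back both views: a PAM
    curve fixes the duration and sweeps amplitude; a PDM curve fixes the
    amplitude and sweeps duration.
    """
    config = config or AnalysisConfig()
    missing = [
        (a, d)
        for d in DURATION_GRID_MS
        for a in AMPLITUDE_GRID_UA
        if session.find_electrical(a, d) is None
    ]
    if missing:
        raise ConfigurationError(f"missing stimulus combinations: {missing}")
    rel: dict[tuple[float, float], float] = {}
    cnt: dict[tuple[float, float], float] = {}
    for d in DURATION_GRID_MS:
        for a in AMPLITUDE_GRID_UA:
            r = trial_response(train, session.find_electrical(a, d), config)
            rel[(a, d)] = r.relative_response
            cnt[(a, d)] = r.evoked_count_mean
    curves: list[ResponseCurve] = []
    for d in DURATION_GRID_MS:
        curves.append(
            ResponseCurve(
                cell_id=train.cell_id,
                mode="PAM",
                fixed_value=float(d),
                x=np.array(AMPLITUDE_GRID_UA),
                y_relative=np.array([rel[(a, d)] for a in AMPLITUDE_GRID_UA]),
                y_count=np.array([cnt[(a, d)] for a in AMPLITUDE_GRID_UA]),
            )
        )
    for a in AMPLITUDE_GRID_UA:
        curves.append(
            ResponseCurve(
                cell_id=train.cell_id,
                mode="PDM",
                fixed_value=float(a),
                x=np.array(DURATION_GRID_MS),
                y_relative=np.array([rel[(a, d)] for d in DURATION_GRID_MS]),
                y_count=np.array([cnt[(a, d)] for d in DURATION_GRID_MS]),
            )
        )
    return curves


def _curve_rho(curve: ResponseCurve) -> float:
    """Spearman rank correlation of the curve; constant curves score 0."""
    y = curve.y_relative
    if np.all(y == y[0]):
        return 0.0
    rho = spearmanr(curve.x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def classify_modulation(
    curves: list[ResponseCurve],
    es_responsive: bool,
    config: AnalysisConfig | None = None,
) -> ModulationLabel:
    """Label a cell well / poorly / un-modulated from its 8 curves.

    "Proportional" is operationalised as Spearman rho >= rho_min (default
    0.8).  well: every curve proportional and the cell ES-responsive at the
    strongest stimulus.  unmodulated: no proportional curve, or not
    ES-responsive.  poor: anything in between.  Rank-based, hence invariant
    to uniform scaling of the responses.
    """
    config = config or AnalysisConfig()
    if not curves:
        raise ConfigurationError("classify_modulation needs at least one curve")
    rho = {(c.mode, c.fixed_value): _curve_rho(c) for c in curves}
    n_prop = sum(1 for v in rho.values() if v >= config.spearman_rho_min)
    if not es_responsive or n_prop == 0:
        label = "unmodulated"
    elif n_prop == len(rho):
        label = "well"
    else:
        label = "poor"
    return ModulationLabel(
        cell_id=curves[0].cell_id, label=label, rho=rho, es_responsive=es_responsive
    )
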