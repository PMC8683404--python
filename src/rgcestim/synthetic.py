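"""Simulated retinal patches with known ground truth.

Each simulated retinal ganglion cell (RGC) fires a homogeneous Poisson
spontaneous train, optionally adds transient light responses (ON / OFF /
ON-OFF) to a 2 s / 2 s full-field alternation, and adds indirect electrically
evoked spikes (10-100 ms latency) to cathodic-first biphasic pulse trains.

The electrical recruitment of a cell is a logistic function of per-phase
charge Q = I*D (nC), anchored to the cell's strength-duration law
I_th(D) = R(1 + C/D): the logistic is calibrated so that the stimulus
amplitude solving that law lands exactly at the 1.5x-baseline crossing of
the relative-response curve the analysis pipeline measures.  The law is
therefore the ground truth that threshold interpolation plus hyperbolic
fitting must recover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import (
    AMPLITUDE_GRID_UA,
    DURATION_GRID_MS,
    REFERENCE_CHANNEL,
    RecordingSession,
    SessionValidationError,
    SpikeTrain,
    StimulusProtocol,
    mea_channel_map,
)

log = logging.getLogger("rgcestim")

#: Constants the recruitment calibration is anchored to; they mirror the
#: analysis defaults (AnalysisConfig) so generator ground truth and pipeline
#: estimates speak the same language.
THRESHOLD_FACTOR = 1.5
EVOKED_WINDOW = (0.010, 0.100)  # s; indirect-response window
LATENCY_MODE_S = 0.040
LATENCY_SD_S = 0.015

LIGHT_TYPES = ("ON", "OFF", "ON_OFF", "none")


@dataclass
class SyntheticCellModel:
    """Generative parameters of one simulated RGC.

    rheobase_uA (R) and chronaxie_ms (C) define the strength-duration law
    I_th(D) = R(1 + C/D); equivalently the threshold charge per phase is
    Q_th(D) = R*(D + C) nC, linear in duration (Weiss form).  evoked_max is
    the asymptotic expected number of evoked spikes per pulse; recruit_slope
    sets the logistic steepness in units of Q_th.  Saturating cells (the
    degeneration phenotype) jump to evoked_max once Q exceeds
    saturation_charge_nC and stay there.
    """

    cell_id: str
    channel_id: int
    spont_rate: float  # Hz
    light_type: str = "none"
    light_gain: float = 20.0  # Hz transient added rate
    rheobase_uA: float = 3.4
    chronaxie_ms: float = 4.2
    evoked_max: float = 8.0  # expected evoked spikes per pulse, asymptotic
    recruit_slope: float = 0.12
    saturating: bool = False
    saturation_charge_nC: float | None = None
    latency_mode: float = LATENCY_MODE_S  # s

    def __post_init__(self) -> None:
        if self.spont_rate < 0:
            raise SessionValidationError("spont_rate must be >= 0")
        if self.rheobase_uA <= 0 or self.chronaxie_ms <= 0:
            raise SessionValidationError("rheobase and chronaxie must be > 0")
        if self.evoked_max < 0:
            raise SessionValidationError("evoked_max must be >= 0")
        if self.light_type not in LIGHT_TYPES:
            raise SessionValidationError(f"unknown light type {self.light_type!r}")
        if not (EVOKED_WINDOW[0] < self.latency_mode < EVOKED_WINDOW[1]):
            raise SessionValidationError("latency_mode outside evoked window")

    def threshold_amplitude(self, duration_ms: float) -> float:
        """Threshold current I_th(D) = R(1 + C/D) in uA."""
        return self.rheobase_uA * (1.0 + self.chronaxie_ms / duration_ms)

    def threshold_charge(self, duration_ms: float) -> float:
        """Threshold charge per phase Q_th(D) = R*(D + C) in nC."""
        return self.rheobase_uA * (duration_ms + self.chronaxie_ms)

    def threshold_spikes(self) -> float:
        """Evoked spikes/pulse at which measured relative response hits 1.5x.

        The evoked window also contains spontaneous spikes, so the measured
        rate is spont + m/w; relative response (factor) = 1 + m/(w*spont)
        crosses THRESHOLD_FACTOR at m = (factor-1) * spont * w.
        """
        w = EVOKED_WINDOW[1] - EVOKED_WINDOW[0]
        return (THRESHOLD_FACTOR - 1.0) * self.spont_rate * w


def evoked_mean(
    model: SyntheticCellModel, amplitude_uA: float, duration_ms: float
) -> float:
    """Expected evoked spikes per pulse for a given stimulus.

    Logistic in per-phase charge Q = I*D, calibrated so that at
    I = R(1 + C/D) the cell adds exactly the number of spikes that puts the
    measured relative response at the 1.5x threshold level.  Monotone
    non-decreasing in amplitude and duration; for saturating cells the
    output clamps at evoked_max once Q reaches saturation_charge_nC.
    """
    if amplitude_uA <= 0 or duration_ms <= 0:
        raise ValueError("amplitude and duration must be positive")
    if model.evoked_max == 0:
        return 0.0
    q = amplitude_uA * duration_ms  # nC per phase
    if (
        model.saturating
        and model.saturation_charge_nC is not None
        and q >= model.saturation_charge_nC
    ):
        return model.evoked_max
    q_th = model.threshold_charge(duration_ms)
    scale = model.recruit_slope * q_th
    m_th = model.threshold_spikes()
    p_th = m_th / model.evoked_max
    if 0.0 < p_th < 1.0:
        # shift the midpoint so the logistic passes through (Q_th, m_th)
        q0 = q_th - scale * math.log(p_th / (1.0 - p_th))
    else:
        # cell too weak ever to cross the threshold level; keep a plain
        # logistic centred on the nominal threshold charge
        q0 = q_th
    z = (q - q0) / scale
    return model.evoked_max / (1.0 + math.exp(-z))


def simulate_spontaneous(
    rate: float, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson spike times in [t0, t1), sorted."""
    if rate < 0:
        raise SessionValidationError("rate must be >= 0")
    if t1 <= t0:
        raise SessionValidationError("t1 must exceed t0")
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_light_trials(
    model: SyntheticCellModel,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Extra spikes from light transients (0.5 s of added Poisson rate).

    ON and ON_OFF cells respond after light onset; OFF and ON_OFF cells after
    light offset (onset + on_duration).  Cells of type "none" add nothing.
    """
    if protocol.kind != "light":
        raise SessionValidationError("simulate_light_trials needs a light protocol")
    if model.light_type == "none" or model.light_gain <= 0:
        return np.empty(0)
    window = 0.5
    starts: list[float] = []
    if model.light_type in ("ON", "ON_OFF"):
        starts.extend(protocol.onsets)
    if model.light_type in ("OFF", "ON_OFF"):
        starts.extend(protocol.onsets + protocol.on_duration_s)
    out: list[np.ndarray] = []
    for s in starts:
        out.append(simulate_spontaneous(model.light_gain, s, s + window, rng))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


def _latency_sampler(model: SyntheticCellModel):
    lo, hi = EVOKED_WINDOW
    a = (lo - model.latency_mode) / LATENCY_SD_S
    b = (hi - model.latency_mode) / LATENCY_SD_S
    return truncnorm(a, b, loc=model.latency_mode, scale=LATENCY_SD_S)


def simulate_electrical_trials(
    model: SyntheticCellModel,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evoked spikes for one pulse train, sorted.

    Per pulse the evoked count is Poisson(evoked_mean) and latencies are
    truncated-normal inside the indirect window (10-100 ms); nothing is ever
    generated inside the artifact blank (0-10 ms).
    """
    if protocol.kind != "electrical":
        raise SessionValidationError(
            "simulate_electrical_trials needs an electrical protocol"
        )
    m = evoked_mean(model, protocol.amplitude_uA, protocol.phase_duration_ms)
    if m == 0.0 or protocol.n_trials == 0:
        return np.empty(0)
    counts = rng.poisson(m, size=protocol.n_trials)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    lat = _latency_sampler(model).rvs(size=total, random_state=rng)
    times = np.repeat(protocol.onsets, counts) + lat
    return np.sort(times)


# ---------------------------------------------------------------------------
# Patch-level generation
# ---------------------------------------------------------------------------

#: Per-severity defaults.  Responsive fractions follow the reported group
#: percentages (light: 66.1 / 48.4 / 0 %; electrical at max stimulus:
#: 56.1 / 59.3 / 27.8 %); rheobase/chronaxie centres follow the reported
#: group means; degenerated groups saturate and evoke fewer spikes.
GROUP_DEFAULTS = {
    "normal": dict(
        fraction_light_responsive=0.661,
        fraction_es_responsive=0.561,
        rheobase_mean=3.37,
        chronaxie_mean=4.21,
        evoked_max_mean=8.0,
        saturating=False,
        group_label="normal",
    ),
    "non_severe": dict(
        fraction_light_responsive=0.484,
        fraction_es_responsive=0.593,
        rheobase_mean=3.94,
        chronaxie_mean=6.32,
        evoked_max_mean=5.0,
        saturating=True,
        group_label="mnu_treated",
    ),
    "severe": dict(
        fraction_light_responsive=0.0,
        fraction_es_responsive=0.278,
        rheobase_mean=4.80,
        chronaxie_mean=6.84,
        evoked_max_mean=4.0,
        saturating=True,
        group_label="mnu_treated",
    ),
}


@dataclass
class PatchSpec:
    """Specification of one simulated retinal patch.

    Group defaults set the responsive fractions, strength-duration centres
    and the degeneration phenotype; any field given explicitly overrides
    them.  `severe` forces fraction_light_responsive = 0.
    """

    group: str = "normal"
    n_cells: int = 50
    seed: int = 0
    fraction_light_responsive: float | None = None
    fraction_es_responsive: float | None = None
    n_pulses: int = 50
    n_light_repeats: int = 20
    spont_rate_mean: float = 8.0  # Hz, lognormal median
    spont_rate_sigma: float = 0.3
    light_gain_mean: float = 25.0  # Hz
    rheobase_mean: float | None = None  # uA, lognormal median
    rheobase_sigma: float = 0.25
    chronaxie_mean: float | None = None  # ms, lognormal median
    chronaxie_sigma: float = 0.35
    evoked_max_mean: float | None = None  # spikes/pulse, lognormal median
    evoked_max_sigma: float = 0.3
    recruit_slope: float = 0.12
    saturating: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_DEFAULTS:
            raise SessionValidationError(f"unknown group {self.group!r}")
        if self.n_cells < 0:
            raise SessionValidationError("n_cells must be >= 0")
        g = GROUP_DEFAULTS[self.group]
        if self.fraction_light_responsive is None:
            self.fraction_light_responsive = g["fraction_light_responsive"]
        if self.fraction_es_responsive is None:
            self.fraction_es_responsive = g["fraction_es_responsive"]
        if self.rheobase_mean is None:
            self.rheobase_mean = g["rheobase_mean"]
        if self.chronaxie_mean is None:
            self.chronaxie_mean = g["chronaxie_mean"]
        if self.evoked_max_mean is None:
            self.evoked_max_mean = g["evoked_max_mean"]
        if self.saturating is None:
            self.saturating = g["saturating"]
        if self.group == "severe":
            self.fraction_light_responsive = 0.0
        for frac in (self.fraction_light_responsive, self.fraction_es_responsive):
            if not 0.0 <= frac <= 1.0:
                raise SessionValidationError("fractions must lie in [0, 1]")


def full_stimulus_protocols(
    n_pulses: int = 50, n_light_repeats: int = 20, start: float = 5.0
) -> list[StimulusProtocol]:
    """The complete session design: one light block then the 5x3 grid.

    Light: 2 s ON / 2 s OFF alternation.  Electrical: per (amplitude,
    duration) combination a train of `n_pulses` pulses at 1 s spacing; 4 s
    quiet gap between blocks so every block has a clean 2 s pre-stimulus
    baseline.
    """
    protocols: list[StimulusProtocol] = []
    t = start
    onsets = t + 4.0 * np.arange(n_light_repeats)
    protocols.append(
        StimulusProtocol(
            protocol_id="light",
            kind="light",
            onsets=onsets,
            on_duration_s=2.0,
            off_duration_s=2.0,
            n_repeats=n_light_repeats,
        )
    )
    t = onsets[-1] + 4.0 + 4.0  # end of last OFF phase + gap
    for dur in DURATION_GRID_MS:
        for amp in AMPLITUDE_GRID_UA:
            onsets = t + 1.0 * np.arange(n_pulses)
            protocols.append(
                StimulusProtocol(
                    protocol_id=f"estim_A{amp:g}uA_D{dur:g}ms",
                    kind="electrical",
                    onsets=onsets,
                    amplitude_uA=float(amp),
                    phase_duration_ms=float(dur),
                )
            )
            t = onsets[-1] + 4.0
    return protocols


def _draw_cell(
    spec: PatchSpec, index: int, channel_id: int, rng: np.random.Generator
) -> SyntheticCellModel:
    spont = spec.spont_rate_mean * math.exp(
        rng.normal(0.0, spec.spont_rate_sigma) - 0.5 * spec.spont_rate_sigma**2
    )
    light_responsive = rng.random() < spec.fraction_light_responsive
    if light_responsive:
        light_type = ("ON", "OFF", "ON_OFF")[rng.integers(3)]
    else:
        light_type = "none"
    es_responsive = rng.random() < spec.fraction_es_responsive
    rheo = spec.rheobase_mean * math.exp(rng.normal(0.0, spec.rheobase_sigma))
    chron = spec.chronaxie_mean * math.exp(rng.normal(0.0, spec.chronaxie_sigma))
    model = SyntheticCellModel(
        cell_id=f"cell_{index:03d}",
        channel_id=channel_id,
        spont_rate=spont,
        light_type=light_type,
        light_gain=spec.light_gain_mean,
        rheobase_uA=rheo,
        chronaxie_ms=chron,
        evoked_max=0.0,
        recruit_slope=spec.recruit_slope,
        saturating=bool(spec.saturating),
        latency_mode=float(
            np.clip(rng.normal(LATENCY_MODE_S, 0.010), 0.015, 0.090)
        ),
    )
    if es_responsive:
        emax = spec.evoked_max_mean * math.exp(
            rng.normal(0.0, spec.evoked_max_sigma)
        )
        # an ES-responsive cell must be able to clear the 1.5x level
        model.evoked_max = max(emax, 3.0 * model.threshold_spikes())
        if model.saturating:
            model.saturation_charge_nC = float(
                rng.uniform(1.2, 1.8) * model.threshold_charge(1.0)
            )
    return model


def make_patch(spec: PatchSpec) -> tuple[RecordingSession, pd.DataFrame]:
    """Simulate one retinal patch: session plus ground-truth table.

    The session carries the full stimulus design (light alternation plus all
    15 electrical blocks).  Ground truth is one row per cell with every
    generative parameter, keyed by cell_id.  A single master seed drives the
    patch; each cell uses a substream derived from (seed, cell index).
    """
    master = np.random.default_rng([int(spec.seed), 0])
    protocols = full_stimulus_protocols(spec.n_pulses, spec.n_light_repeats)
    t_end = max(p.onsets[-1] for p in protocols) + 4.0
    channel_ids = [c for c, _, _ in mea_channel_map() if c != REFERENCE_CHANNEL]
    trains: list[SpikeTrain] = []
    rows: list[dict] = []
    for i in range(spec.n_cells):
        rng = np.random.default_rng([int(spec.seed), 1 + i])
        channel = channel_ids[int(master.integers(len(channel_ids)))]
        model = _draw_cell(spec, i, channel, rng)
        parts = [simulate_spontaneous(model.spont_rate, 0.0, t_end, rng)]
        for p in protocols:
            if p.kind == "light":
                parts.append(simulate_light_trials(model, p, rng))
            else:
                parts.append(simulate_electrical_trials(model, p, rng))
        times = np.unique(np.concatenate(parts))
        trains.append(
            SpikeTrain(
                cell_id=model.cell_id,
                channel_id=model.channel_id,
                unit_index=0,
                times=times,
            )
        )
        rows.append(asdict(model))
    session = RecordingSession(
        session_id=f"synthetic_{spec.group}_seed{spec.seed}",
        spike_trains=trains,
        protocols=protocols,
        group_label=GROUP_DEFAULTS[spec.group]["group_label"],
    )
    truth = pd.DataFrame(rows)
    if not truth.empty:
        truth = truth.set_index("cell_id", drop=False)
    return session, truth


# ---------------------------------------------------------------------------
# Raw-trace rendering (for the detection stage)
# ---------------------------------------------------------------------------

def default_spike_template(
    sampling_rate: float = 25000.0, peak_uV: float = 1.0
) -> np.ndarray:
    """Canonical biphasic extracellular somatic waveform, ~1.6 ms long.

    Negative-first (sodium trough) followed by a smaller positive
    repolarisation lobe; peak (most negative) value equals -peak_uV.
    """
    n = int(round(1.6e-3 * sampling_rate))
    t = np.arange(n) / sampling_rate
    trough = -np.exp(-0.5 * ((t - 0.4e-3) / 0.12e-3) ** 2)
    bump = 0.35 * np.exp(-0.5 * ((t - 0.9e-3) / 0.25e-3) ** 2)
    w = trough + bump
    return peak_uV * w / np.abs(w).max()


def render_raw_trace(
    session: RecordingSession,
    waveform_template: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    duration_s: float | None = None,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Render per-channel voltage traces from the session's spike trains.

    Each spike stamps the template at its sample index (template peak aligned
    to the spike time); overlapping placements are summed (and logged);
    Gaussian noise of SD noise_sd (uV) is added.  Returns (traces,
    truth_sample_indices) keyed by channel id.
    """
    fs = session.sampling_rate
    template = np.asarray(waveform_template, dtype=float)
    peak_offset = int(np.argmin(template))
    if duration_s is None:
        duration_s = max(
            (t.times[-1] for t in session.spike_trains if t.times.size),
            default=1.0,
        ) + 0.05
    n_samples = int(math.ceil(duration_s * fs))
    traces: dict[int, np.ndarray] = {}
    truth: dict[int, np.ndarray] = {}
    for cid in sorted({t.channel_id for t in session.spike_trains}):
        trace = rng.normal(0.0, noise_sd, size=n_samples)
        indices: list[int] = []
        n_overlap = 0
        last_end = -1
        for train in session.spike_trains:
            if train.channel_id != cid:
                continue
            for t_spike in train.times:
                idx = int(round(t_spike * fs))
                start = idx - peak_offset
                if start < 0 or start + template.size > n_samples:
                    continue
                if start <= last_end:
                    n_overlap += 1
                trace[start : start + template.size] += template
                last_end = start + template.size - 1
                indices.append(idx)
        if n_overlap:
            log.warning(
                "channel %d: %d overlapping template placements summed",
                cid,
                n_overlap,
            )
        traces[cid] = trace
        truth[cid] = np.array(sorted(indices), dtype=np.int64)
    return traces, truth
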