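"""Self-contained validation studies on synthetic ground truth.

Each study simulates data with the synthetic generator, runs the analysis
pipeline on it, and measures how well known generative quantities are
recovered.  They are the package's end-to-end checks: parameter recovery of
the strength-duration law, spike-detection performance on rendered traces,
calibration of the PSTH confidence bound and of the light-response
classifier, and the qualitative threshold-monotonicity pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import detect as detect_spikes
from .detect import highpass
from .core import (
    AMPLITUDE_GRID_UA,
    DURATION_GRID_MS,
    AnalysisConfig,
    RecordingSession,
    SpikeTrain,
    StimulusProtocol,
)
from .estim import ResponseCurve, stim_psth
from .light import classify_light
from .pipeline import run_pipeline
from .sdcurve import threshold_from_curve
from .synthetic import (
    EVOKED_WINDOW,
    PatchSpec,
    SyntheticCellModel,
    default_spike_template,
    evoked_mean,
    make_patch,
    render_raw_trace,
    simulate_spontaneous,
)

log = logging.getLogger("rgcestim")


def _sub_seed(seed: int, k: int) -> int:
    return int((int(seed) + 7919 * k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Strength-duration parameter recovery
# ---------------------------------------------------------------------------

#: Conditions of the parameter-recovery study.  Rheobase and chronaxie are
#: drawn so that every threshold falls inside the tested 10-30 uA x
#: 0.5-2 ms grid and the chronaxie is resolvable by the tested durations
#: (a chronaxie far above the longest tested duration leaves only the
#: product R*C identifiable).  High spontaneous rates give the 2 s
#: pre-stimulus baseline enough spikes for a precise relative response.
RECOVERY_SPEC = dict(
    group="normal",
    n_cells=60,
    n_pulses=100,
    fraction_es_responsive=1.0,
    fraction_light_responsive=0.0,
    saturating=False,
    evoked_max_mean=10.0,
    evoked_max_sigma=0.05,
    spont_rate_mean=40.0,
    rheobase_mean=7.0,
    rheobase_sigma=0.1,
    chronaxie_mean=1.2,
    chronaxie_sigma=0.2,
)


@dataclass
class RecoveryResult:
    n_cells: int
    n_fitted: int
    median_rheobase_rel_err: float
    median_chronaxie_rel_err: float


def recovery_study(seed: int = 1) -> RecoveryResult:
    """Simulate a patch, run the full pipeline, compare SD fits to truth.

    Returns median relative errors of rheobase and chronaxie over all
    fitted cells.
    """
    spec = PatchSpec(seed=_sub_seed(seed, 1), **RECOVERY_SPEC)
    session, truth = make_patch(spec)
    bundle = run_pipeline(session)
    fits = bundle.sd_fits.set_index("cell_id")
    joined = truth.join(fits, rsuffix="_est").dropna(subset=["rheobase_uA_est"])
    err_r = np.abs(joined["rheobase_uA_est"] - joined["rheobase_uA"]) / joined[
        "rheobase_uA"
    ]
    err_c = np.abs(joined["chronaxie_ms_est"] - joined["chronaxie_ms"]) / joined[
        "chronaxie_ms"
    ]
    return RecoveryResult(
        n_cells=len(truth),
        n_fitted=len(joined),
        median_rheobase_rel_err=float(np.median(err_r)),
        median_chronaxie_rel_err=float(np.median(err_c)),
    )


# ---------------------------------------------------------------------------
# Spike-detection performance
# ---------------------------------------------------------------------------

@dataclass
class DetectionResultSummary:
    n_true: int
    n_detected: int
    recall: float
    precision: float


def detection_study(
    seed: int = 1,
    n_spikes: int = 500,
    duration_s: float = 25.0,
    snr: float = 8.0,
    noise_sd: float = 5.0,
    sd_multiple: float = 4.0,
) -> DetectionResultSummary:
    """Render a trace with known spikes at the given SNR and detect them.

    A detection within +/-0.5 ms of an unmatched true spike counts as a
    true positive.
    """
    rng = np.random.default_rng(_sub_seed(seed, 2))
    fs = 25000.0
    t = np.sort(rng.uniform(0.1, duration_s - 0.1, n_spikes * 2))
    t = t[np.concatenate([[True], np.diff(t) > 0.003])][:n_spikes]
    session = RecordingSession("sim", spike_trains=[SpikeTrain("c", 1, 0, t)])
    template = default_spike_template(fs, peak_uV=snr * noise_sd)
    traces, truth = render_raw_trace(session, template, noise_sd, rng, duration_s)
    filtered = highpass(traces[1], 100.0, fs)
    result = detect_spikes(filtered, fs, sd_multiple=sd_multiple)
    detected = result.spike_sample_indices
    tol = int(0.0005 * fs)
    used = np.zeros(truth[1].size, dtype=bool)
    tp = 0
    for d in detected:
        j = int(np.argmin(np.abs(truth[1] - d)))
        if abs(truth[1][j] - d) <= tol and not used[j]:
            used[j] = True
            tp += 1
    return DetectionResultSummary(
        n_true=int(truth[1].size),
        n_detected=int(detected.size),
        recall=tp / truth[1].size if truth[1].size else float("nan"),
        precision=tp / detected.size if detected.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# Calibration of significance machinery
# ---------------------------------------------------------------------------

def psth_bound_exceedance(
    seed: int = 1, n_sims: int = 500, rate_hz: float = 10.0, n_trials: int = 50
) -> float:
    """Fraction of PSTH bins above the 99% bound for flat Poisson cells."""
    config = AnalysisConfig()
    rng = np.random.default_rng(_sub_seed(seed, 3))
    exceed = total = 0
    onsets = 3.0 + np.arange(n_trials) * 1.0
    proto = StimulusProtocol(
        "e", "electrical", onsets, amplitude_uA=30.0, phase_duration_ms=2.0
    )
    for _ in range(n_sims):
        times = simulate_spontaneous(rate_hz, 0.0, onsets[-1] + 2.0, rng)
        ps = stim_psth(SpikeTrain("c", 1, 0, times), proto, config)
        exceed += int(np.sum(ps.counts > ps.confidence_bound))
        total += ps.counts.size
    return exceed / total


def light_false_positive_rate(
    seed: int = 1, n_cells: int = 500, rate_hz: float = 8.0
) -> float:
    """Fraction of light-unresponsive Poisson cells labelled responsive."""
    config = AnalysisConfig()
    rng = np.random.default_rng(_sub_seed(seed, 4))
    onsets = 5.0 + 4.0 * np.arange(20)
    proto = StimulusProtocol(
        "light", "light", onsets, on_duration_s=2.0, off_duration_s=2.0, n_repeats=20
    )
    fp = 0
    for _ in range(n_cells):
        times = simulate_spontaneous(rate_hz, 0.0, onsets[-1] + 5.0, rng)
        label = classify_light(SpikeTrain("c", 1, 0, times), proto, config).label
        fp += int(label != "none")
    return fp / n_cells


# ---------------------------------------------------------------------------
# Threshold monotonicity
# ---------------------------------------------------------------------------

def threshold_monotonicity_violations(seed: int = 1, n_cells: int = 20) -> int:
    """Violations of the qualitative strength-duration pattern.

    For cells obeying the SD law, the estimated threshold amplitude must be
    non-increasing in the fixed pulse duration and the estimated threshold
    duration non-increasing in the fixed amplitude.  Thresholds are taken
    from the noise-free expected response curves (censored estimates count
    as above-range).  Returns the number of ordering violations (0 = the
    pattern holds).
    """
    rng = np.random.default_rng(_sub_seed(seed, 5))
    w = EVOKED_WINDOW[1] - EVOKED_WINDOW[0]
    violations = 0
    for i in range(n_cells):
        m = SyntheticCellModel(
            cell_id=f"c{i}",
            channel_id=1,
            spont_rate=float(rng.uniform(5, 40)),
            rheobase_uA=float(rng.uniform(3, 9)),
            chronaxie_ms=float(rng.uniform(0.5, 4.0)),
            evoked_max=float(rng.uniform(8, 15)),
        )

        def rel(a, d):
            return 1.0 + evoked_mean(m, a, d) / (w * m.spont_rate)

        amp_thresholds = []
        for d in DURATION_GRID_MS:
            x = np.array(AMPLITUDE_GRID_UA)
            c = ResponseCurve("c", "PAM", d, x, np.array([rel(a, d) for a in x]), x * 0)
            est = threshold_from_curve(c)
            amp_thresholds.append(np.inf if est.censored else est.threshold_value)
        dur_thresholds = []
        for a in AMPLITUDE_GRID_UA:
            x = np.array(DURATION_GRID_MS)
            c = ResponseCurve("c", "PDM", a, x, np.array([rel(a, d) for d in x]), x * 0)
            est = threshold_from_curve(c)
            dur_thresholds.append(np.inf if est.censored else est.threshold_value)
        for seq in (amp_thresholds, dur_thresholds):
            for a, b in zip(seq, seq[1:]):
                # inf = censored (above range); inf -> inf is not a violation
                if np.isfinite(b) or np.isfinite(a):
                    violations += int(b > a + 1e-9)
    return violations
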