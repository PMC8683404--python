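"""Light-response classification and retinal-degeneration severity calls.

Cells are scored on the 0.5 s windows following light onset and light
offset of a full-field 2 s ON / 2 s OFF alternation.  A phase is called
responsive when its pooled spike count exceeds the 99% upper quantile of a
Poisson null at the cell's whole-block mean rate; the ON/OFF/ON-OFF/none
label follows from the two flags.  A patch's severity class rests on its
light-responsive fraction: untreated patches are normal; treated patches
with no light-responsive cells are severe, otherwise non-severe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .core import (
    AnalysisConfig,
    ConfigurationError,
    RecordingSession,
    SpikeTrain,
    StimulusProtocol,
)

log = logging.getLogger("rgcestim")


@dataclass
class LightClassification:
    cell_id: str
    label: str  # ON | OFF | ON_OFF | none
    onset_score: float  # window rate / block mean rate
    offset_score: float
    onset_significant: bool = False
    offset_significant: bool = False


@dataclass
class SeverityCall:
    patch_id: str
    group_label: str
    ls_fraction: float  # percent
    severity: str  # normal | non_severe | severe


def _phase_test(
    train: SpikeTrain,
    window_starts: np.ndarray,
    window: float,
    block_rate: float,
    confidence: float,
) -> tuple[float, bool]:
    """Score one phase: pooled window rate ratio + Poisson significance."""
    count = int(train.counts_in_windows(window_starts, window).sum())
    total_time = window * window_starts.size
    rate = count / total_time if total_time > 0 else 0.0
    score = rate / block_rate if block_rate > 0 else 0.0
    mu = block_rate * total_time
    significant = count > poisson.ppf(confidence, mu) if mu > 0 else count > 0
    return score, bool(significant)


def classify_light(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    config: AnalysisConfig | None = None,
) -> LightClassification:
    """Classify one cell's light response as ON, OFF, ON_OFF or none."""
    config = config or AnalysisConfig()
    if protocol.kind != "light":
        raise ConfigurationError("classify_light needs a light protocol")
    if protocol.n_trials < 5:
        raise ConfigurationError("need at least 5 light repeats")
    period = protocol.on_duration_s + protocol.off_duration_s
    block_start = float(protocol.onsets[0])
    block_end = float(protocol.onsets[-1]) + period
    n_block = train.count_between(block_start, block_end)
    if n_block == 0:
        return LightClassification(train.cell_id, "none", 0.0, 0.0)
    block_rate = n_block / (block_end - block_start)
    w = config.light_window_s
    onset_score, on_sig = _phase_test(
        train, protocol.onsets, w, block_rate, config.light_confidence
    )
    offset_score, off_sig = _phase_test(
        train,
        protocol.onsets + protocol.on_duration_s,
        w,
        block_rate,
        config.light_confidence,
    )
    if on_sig and off_sig:
        label = "ON_OFF"
    elif on_sig:
        label = "ON"
    elif off_sig:
        label = "OFF"
    else:
        label = "none"
    return LightClassification(
        train.cell_id, label, onset_score, offset_score, on_sig, off_sig
    )


def classify_session_light(
    session: RecordingSession, config: AnalysisConfig | None = None
) -> list[LightClassification]:
    """Light classification for every cell of the session."""
    protos = session.light_protocols()
    if not protos:
        raise ConfigurationError("session has no light protocol")
    return [classify_light(t, protos[0], config) for t in session.spike_trains]


def ls_fraction(
    session: RecordingSession, config: AnalysisConfig | None = None
) -> float:
    """Light-responsive percentage of the patch: 100 * responsive / total.

    A cell counts as light-responsive when either phase (onset or offset)
    is significant, i.e. its label is anything but "none".
    """
    if not session.spike_trains:
        raise ConfigurationError("ls_fraction undefined for an empty session")
    labels = classify_session_light(session, config)
    responsive = sum(1 for c in labels if c.label != "none")
    return 100.0 * responsive / len(labels)


def classify_severity(session: RecordingSession, ls_pct: float) -> SeverityCall:
    """Assign the patch's degeneration severity class.

    Untreated -> normal.  Treated patches with zero light-responsive cells
    -> severe; treated with any light response -> non-severe.
    """
    if session.group_label == "normal":
        severity = "normal"
    elif ls_pct == 0.0:
        severity = "severe"
    else:
        severity = "non_severe"
    return SeverityCall(
        patch_id=session.session_id,
        group_label=session.group_label,
        ls_fraction=ls_pct,
        severity=severity,
    )
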