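"""End-to-end analysis pipeline for one recorded (or simulated) patch.

Chains the stages: light classification and severity call, per-cell
electrical trial responses over the full 5x3 stimulus grid, response
curves, modulation labelling, ES-responsiveness, threshold estimation on
both modulation axes, strength-duration fits, and charge metrics.  Every
table is keyed by cell_id; the run is deterministic given (session,
config).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estim, light, sdcurve
from .core import (
    AMPLITUDE_GRID_UA,
    DURATION_GRID_MS,
    AnalysisConfig,
    ConfigurationError,
    RecordingSession,
)

log = logging.getLogger("rgcestim")


@dataclass
class ReportBundle:
    """All pipeline output tables, each keyed by cell_id."""

    session_id: str
    severity: light.SeverityCall | None
    light_labels: pd.DataFrame
    responses: pd.DataFrame
    modulation: pd.DataFrame
    thresholds: pd.DataFrame
    sd_fits: pd.DataFrame
    threshold_summary: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        """Write every table as CSV; deterministic for identical bundles."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "light_labels": self.light_labels,
            "responses": self.responses,
            "modulation": self.modulation,
            "thresholds": self.thresholds,
            "sd_fits": self.sd_fits,
            "table1_style": self.threshold_summary,
        }
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.9g")
        with open(out / "summary.txt", "w") as fh:
            for k in sorted(self.summary):
                fh.write(f"{k}: {self.summary[k]}\n")
        return out


def has_full_grid(session: RecordingSession) -> bool:
    return all(
        session.find_electrical(a, d) is not None
        for a in AMPLITUDE_GRID_UA
        for d in DURATION_GRID_MS
    )


def run_pipeline(
    session: RecordingSession, config: AnalysisConfig | None = None
) -> ReportBundle:
    """Run the whole analysis on one session.

    Requires at least one electrical protocol.  Threshold pairs from both
    modulation axes — (fixed duration, interpolated threshold amplitude)
    and (interpolated threshold duration, fixed amplitude) — are points on
    the same strength-duration curve and are pooled for the per-cell
    hyperbolic fit; censored estimates are excluded.
    """
    config = config or AnalysisConfig()
    if not session.electrical_protocols():
        raise ConfigurationError("session has no electrical protocols")
    full_grid = has_full_grid(session)
    level = config.response_threshold_factor

    # --- light stage ----------------------------------------------------
    light_rows = []
    severity = None
    if session.light_protocols() and session.spike_trains:
        labels = light.classify_session_light(session, config)
        for c in labels:
            light_rows.append(
                {
                    "cell_id": c.cell_id,
                    "label": c.label,
                    "onset_score": c.onset_score,
                    "offset_score": c.offset_score,
                }
            )
        ls = 100.0 * sum(1 for c in labels if c.label != "none") / len(labels)
        severity = light.classify_severity(session, ls)
    light_df = pd.DataFrame(
        light_rows, columns=["cell_id", "label", "onset_score", "offset_score"]
    )

    # --- electrical stage ------------------------------------------------
    resp_rows, mod_rows, thr_rows, fit_rows = [], [], [], []
    for train in session.spike_trains:
        for proto in session.electrical_protocols():
            r = estim.trial_response(train, proto, config)
            resp_rows.append(
                {
                    "cell_id": r.cell_id,
                    "protocol_id": r.protocol_id,
                    "amplitude_uA": r.amplitude_uA,
                    "phase_duration_ms": r.phase_duration_ms,
                    "baseline_rate": r.baseline_rate,
                    "evoked_rate": r.evoked_rate,
                    "evoked_count_mean": r.evoked_count_mean,
                    "relative_response": r.relative_response,
                    "n_trials": r.n_trials,
                }
            )
        if not full_grid:
            continue
        es = estim.is_es_responsive(train, session, config)
        curves = estim.response_curves(train, session, config)
        mod = estim.classify_modulation(curves, es, config)
        mod_rows.append(
            {
                "cell_id": mod.cell_id,
                "label": mod.label,
                "es_responsive": es,
                "min_rho": min(mod.rho.values()),
            }
        )
        pairs_d, pairs_i = [], []
        for curve in curves:
            est = sdcurve.threshold_from_curve(curve, level=level)
            thr_rows.append(
                {
                    "cell_id": est.cell_id,
                    "mode": est.mode,
                    "fixed_value": est.fixed_value,
                    "threshold_value": est.threshold_value,
                    "method": est.method,
                }
            )
            # only in-range (interpolated) thresholds feed the SD fit:
            # extrapolated values lie outside the measured stimulus range
            # and would leverage the hyperbola disproportionately
            if est.method != "interpolated":
                continue
            if est.mode == "amplitude_at_fixed_duration":
                pairs_d.append(est.fixed_value)
                pairs_i.append(est.threshold_value)
            else:
                pairs_d.append(est.threshold_value)
                pairs_i.append(est.fixed_value)
        if len(pairs_d) >= 2 and np.unique(np.round(pairs_d, 9)).size >= 2:
            fit = sdcurve.fit_sd(pairs_d, pairs_i, cell_id=train.cell_id)
            fit_rows.append(
                {
                    "cell_id": fit.cell_id,
                    "rheobase_uA": fit.rheobase_uA,
                    "chronaxie_ms": fit.chronaxie_ms,
                    "rss": fit.rss,
                    "n_points": fit.n_points,
                    "converged": fit.converged,
                }
            )
        else:
            log.info("cell %s: too few threshold points for an SD fit", train.cell_id)

    responses = pd.DataFrame(
        resp_rows,
        columns=[
            "cell_id",
            "protocol_id",
            "amplitude_uA",
            "phase_duration_ms",
            "baseline_rate",
            "evoked_rate",
            "evoked_count_mean",
            "relative_response",
            "n_trials",
        ],
    )
    modulation = pd.DataFrame(
        mod_rows, columns=["cell_id", "label", "es_responsive", "min_rho"]
    )
    thresholds = pd.DataFrame(
        thr_rows,
        columns=["cell_id", "mode", "fixed_value", "threshold_value", "method"],
    )
    sd_fits = pd.DataFrame(
        fit_rows,
        columns=["cell_id", "rheobase_uA", "chronaxie_ms", "rss", "n_points", "converged"],
    )

    n_cells = len(session.spike_trains)
    summary: dict = {"n_cells": n_cells}
    if len(modulation):
        k_well = int((modulation["label"] == "well").sum())
        summary["well_modulated"] = sdcurve.format_fraction(k_well, n_cells)
        summary["es_responsive_pct"] = (
            100.0 * int(modulation["es_responsive"].sum()) / n_cells
        )
    if severity is not None:
        summary["ls_fraction_pct"] = severity.ls_fraction
        summary["severity"] = severity.severity
    if len(sd_fits):
        # medians: fits on cells whose chronaxie far exceeds the tested
        # durations can run away (only R*C identifiable there)
        summary["rheobase_median_uA"] = float(sd_fits["rheobase_uA"].median())
        summary["chronaxie_median_ms"] = float(sd_fits["chronaxie_ms"].median())

    thr_summary = (
        sdcurve.threshold_summary_table(thresholds, config.electrode_diameter_um)
        if len(thresholds)
        else pd.DataFrame()
    )
    return ReportBundle(
        session_id=session.session_id,
        severity=severity,
        light_labels=light_df,
        responses=responses,
        modulation=modulation,
        thresholds=thresholds,
        sd_fits=sd_fits,
        threshold_summary=thr_summary,
        summary=summary,
    )
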