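"""Electrically evoked response quantification: baselines, evoked windows,
relative responses, PSTHs, modulation curves and labels."""

import math

import numpy as np
import pytest

from rgcestim.core import (
    AnalysisConfig,
    ConfigurationError,
    RecordingSession,
    SpikeTrain,
    StimulusProtocol,
    AMPLITUDE_GRID_UA,
    DURATION_GRID_MS,
)
from rgcestim.estim import (
    ResponseCurve,
    baseline_rate,
    classify_modulation,
    evoked_rate,
    is_es_responsive,
    relative_response,
    response_curves,
    stim_psth,
    trial_response,
)
from rgcestim.synthetic import full_stimulus_protocols

from conftest import make_electrical


class TestBaselineRate:
    def test_uniform_ten_spikes_gives_five_hz(self, electrical_protocol, config):
        times = np.linspace(1.05, 2.95, 10)  # inside the 2 s pre-stimulus window
        cell = SpikeTrain("c", 1, 0, times)
        assert baseline_rate(cell, electrical_protocol, config) == pytest.approx(5.0)

    def test_empty_window_is_zero(self, electrical_protocol, config):
        assert baseline_rate(SpikeTrain("c", 1, 0, []), electrical_protocol, config) == 0.0

    def test_poisson_rate_within_standard_error(self, electrical_protocol, config):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.0, 3.0, rng.poisson(20.0 * 3.0)))
        cell = SpikeTrain("c", 1, 0, np.unique(times))
        est = baseline_rate(cell, electrical_protocol, config)
        assert abs(est - 20.0) < 4 * np.sqrt(40.0) / 2.0

    def test_insufficient_span_rejected(self, config):
        proto = make_electrical(start=1.0)
        with pytest.raises(ConfigurationError, match="pre-stimulus"):
            baseline_rate(SpikeTrain("c", 1, 0, []), proto, config)


class TestEvokedRate:
    def test_one_spike_per_trial_at_50ms(self, config):
        proto = make_electrical(n_pulses=10)
        times = proto.onsets + 0.050
        cell = SpikeTrain("c", 1, 0, times)
        assert evoked_rate(cell, proto, config) == pytest.approx(1 / 0.090)

    def test_artifact_blank_spikes_ignored(self, config):
        proto = make_electrical(n_pulses=10)
        cell = SpikeTrain("c", 1, 0, proto.onsets + 0.005)
        assert evoked_rate(cell, proto, config) == 0.0

    def test_window_partition_property(self, config):
        """Evoked counts never include artifact-blank spikes."""
        rng = np.random.default_rng(1)
        proto = make_electrical(n_pulses=20)
        for _ in range(10):
            lat = rng.uniform(0.0, 0.15, size=proto.n_trials)
            times = np.unique(proto.onsets + lat)
            cell = SpikeTrain("c", 1, 0, times)
            expected = np.sum((lat >= 0.010) & (lat < 0.100)) / 20 / 0.090
            assert evoked_rate(cell, proto, config) == pytest.approx(expected)


class TestRelativeResponse:
    @pytest.mark.parametrize(
        "base,evoked,expected",
        [(10.0, 15.0, 1.5), (0.0, 0.0, 0.0), (4.0, 10.0, 2.5)],
    )
    def test_definitions(self, base, evoked, expected):
        assert relative_response(base, evoked) == pytest.approx(expected)

    def test_silent_baseline_with_evoked_is_infinite(self):
        assert math.isinf(relative_response(0.0, 3.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_response(-1.0, 2.0)


def grid_session(cell_times, n_pulses=10):
    protocols = full_stimulus_protocols(n_pulses=n_pulses)
    return RecordingSession(
        "s",
        spike_trains=[SpikeTrain("c", 1, 0, cell_times)],
        protocols=protocols,
    )


def synth_session_for_cell(rel_by_combo, n_pulses=20, baseline_hz=10.0):
    """Build a deterministic session whose relative responses are exact.

    Places `baseline_hz * 2` spikes in each block's baseline window and, per
    trial, round(rel * baseline_hz * 0.09) spikes at fixed latencies.
    """
    protocols = full_stimulus_protocols(n_pulses=n_pulses)
    times = []
    for p in protocols:
        if p.kind != "electrical":
            continue
        t0 = p.onsets[0] - 2.0
        times.append(np.linspace(t0 + 0.01, p.onsets[0] - 0.01, int(baseline_hz * 2)))
        k = rel_by_combo.get((p.amplitude_uA, p.phase_duration_ms), 0)
        if k > 0:
            lat = np.linspace(0.02, 0.09, k)
            times.append((p.onsets[:, None] + lat[None, :]).ravel())
    all_times = np.unique(np.concatenate(times))
    return RecordingSession(
        "s",
        spike_trains=[SpikeTrain("c", 1, 0, all_times)],
        protocols=protocols,
    )


class TestEsResponsive:
    def test_threshold_is_strict(self, config):
        # 1 spike/trial at max stimulus over 10 Hz baseline: rel = 11.1/10 = 1.11
        sess = synth_session_for_cell({(30.0, 2.0): 1}, baseline_hz=10.0)
        assert not is_es_responsive(sess.spike_trains[0], sess, config)
        # 2 spikes/trial: rel = 22.2/10 = 2.2 >= 1.5
        sess2 = synth_session_for_cell({(30.0, 2.0): 2}, baseline_hz=10.0)
        assert is_es_responsive(sess2.spike_trains[0], sess2, config)

    def test_silent_baseline_with_evoked_spikes_is_responsive(self, config):
        sess = synth_session_for_cell({(30.0, 2.0): 1}, baseline_hz=0.0)
        assert is_es_responsive(sess.spike_trains[0], sess, config)

    def test_missing_max_protocol_rejected(self, config):
        sess = RecordingSession(
            "s",
            spike_trains=[SpikeTrain("c", 1, 0, [])],
            protocols=[make_electrical(amplitude=10.0, duration=0.5)],
        )
        with pytest.raises(ConfigurationError):
            is_es_responsive(sess.spike_trains[0], sess, config)

    def test_severe_patch_responsive_fraction_binomial(self, config):
        """The measured ES-responsive fraction of a severe-degeneration
        patch tracks the generative fraction (~28%) to binomial accuracy.
        The spontaneous rate is set high enough that the sampling error of
        the single-point 1.5x criterion is negligible next to the binomial
        spread."""
        from rgcestim.synthetic import PatchSpec, make_patch

        spec = PatchSpec(
            group="severe", n_cells=200, seed=1, n_pulses=50, spont_rate_mean=25.0
        )
        session, _ = make_patch(spec)
        frac = np.mean(
            [is_es_responsive(t, session, config) for t in session.spike_trains]
        )
        p = spec.fraction_es_responsive
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 200)

    def test_threshold_factor_consistency(self):
        """is_es_responsive follows the configured factor, whatever it is."""
        sess = synth_session_for_cell({(30.0, 2.0): 2}, baseline_hz=10.0)  # rel 2.22
        cell = sess.spike_trains[0]
        assert is_es_responsive(cell, sess, AnalysisConfig(response_threshold_factor=2.0))
        assert not is_es_responsive(
            cell, sess, AnalysisConfig(response_threshold_factor=2.5)
        )


class TestStimPSTH:
    def test_zero_spike_cell(self, config):
        proto = make_electrical(n_pulses=10)
        ps = stim_psth(SpikeTrain("c", 1, 0, []), proto, config)
        assert np.all(ps.counts == 0) and ps.confidence_bound >= 0

    def test_strong_evoked_cell_exceeds_bound(self, config):
        proto = make_electrical(n_pulses=30)
        rng = np.random.default_rng(0)
        spont = np.sort(rng.uniform(0.0, proto.onsets[-1] + 1, 300))
        evoked = (proto.onsets[:, None] + np.array([0.03, 0.05])[None, :]).ravel()
        cell = SpikeTrain("c", 1, 0, np.unique(np.concatenate([spont, evoked])))
        ps = stim_psth(cell, proto, config)
        post = ps.counts[ps.bin_edges[:-1] >= 0.0]
        assert np.any(post > ps.confidence_bound)

    def test_bound_at_least_baseline_mean(self, config):
        proto = make_electrical(n_pulses=10)
        rng = np.random.default_rng(1)
        cell = SpikeTrain("c", 1, 0, np.sort(rng.uniform(0, 14, 200)))
        ps = stim_psth(cell, proto, config)
        assert ps.confidence_bound >= ps.baseline_mean


class TestResponseCurves:
    def test_pam_and_pdm_share_measurements(self, config):
        sess = synth_session_for_cell({(a, d): 2 for a in AMPLITUDE_GRID_UA for d in DURATION_GRID_MS})
        curves = response_curves(sess.spike_trains[0], sess, config)
        pam2 = next(c for c in curves if c.mode == "PAM" and c.fixed_value == 2.0)
        pdm30 = next(c for c in curves if c.mode == "PDM" and c.fixed_value == 30.0)
        assert pam2.y_relative[-1] == pytest.approx(pdm30.y_relative[-1])

    def test_missing_combination_listed(self, config):
        protocols = full_stimulus_protocols(n_pulses=5)[:-1]  # drop one combo
        sess = RecordingSession(
            "s", spike_trains=[SpikeTrain("c", 1, 0, [])], protocols=protocols
        )
        with pytest.raises(ConfigurationError, match="missing stimulus combinations"):
            response_curves(sess.spike_trains[0], sess, config)

    def test_curve_count_and_axes(self, config):
        sess = synth_session_for_cell({})
        curves = response_curves(sess.spike_trains[0], sess, config)
        assert len(curves) == 8
        assert sum(c.mode == "PAM" for c in curves) == 3
        assert sum(c.mode == "PDM" for c in curves) == 5


def _curves(y_fn):
    out = []
    for d in DURATION_GRID_MS:
        x = np.array(AMPLITUDE_GRID_UA)
        out.append(ResponseCurve("c", "PAM", d, x, y_fn(x * d), np.zeros_like(x)))
    for a in AMPLITUDE_GRID_UA:
        x = np.array(DURATION_GRID_MS)
        out.append(ResponseCurve("c", "PDM", a, x, y_fn(a * x), np.zeros_like(x)))
    return out


class TestClassifyModulation:
    def test_strictly_increasing_is_well(self, config):
        curves = _curves(lambda q: 1.0 + 0.1 * q)
        assert classify_modulation(curves, es_responsive=True, config=config).label == "well"

    def test_flat_is_unmodulated(self, config):
        curves = _curves(lambda q: np.ones_like(q))
        assert (
            classify_modulation(curves, es_responsive=True, config=config).label
            == "unmodulated"
        )

    def test_not_es_responsive_is_unmodulated(self, config):
        curves = _curves(lambda q: 1.0 + 0.1 * q)
        assert (
            classify_modulation(curves, es_responsive=False, config=config).label
            == "unmodulated"
        )

    def test_mixed_curves_are_poor(self, config):
        curves = _curves(lambda q: 1.0 + 0.1 * q)
        flat = ResponseCurve(
            "c", "PAM", 0.5, np.array(AMPLITUDE_GRID_UA), np.ones(5), np.zeros(5)
        )
        curves[0] = flat
        assert classify_modulation(curves, es_responsive=True, config=config).label == "poor"

    def test_generator_mixture_fractions(self, config):
        """Classifying the expected (noise-free) response curves of a 60/40
        mixture of modulated and flat generator cells recovers the mixture
        weights to within binomial sampling error."""
        from rgcestim.synthetic import EVOKED_WINDOW, SyntheticCellModel, evoked_mean

        rng = np.random.default_rng(0)
        w = EVOKED_WINDOW[1] - EVOKED_WINDOW[0]
        n, p_mod = 100, 0.6
        n_well = n_unmod = 0
        n_modulated = 0
        for i in range(n):
            modulated = rng.random() < p_mod
            n_modulated += int(modulated)
            m = SyntheticCellModel(
                cell_id=f"c{i}",
                channel_id=1,
                spont_rate=float(rng.uniform(10, 40)),
                rheobase_uA=float(rng.uniform(3.5, 4.5)),
                chronaxie_ms=float(rng.uniform(0.8, 1.2)),
                evoked_max=20.0 if modulated else 0.0,
                recruit_slope=0.8,
            )
            curves = _curves(
                lambda q, m=m: np.array(
                    [1.0 + evoked_mean(m, qq, 1.0) / (w * m.spont_rate) for qq in q]
                )
            )
            label = classify_modulation(curves, es_responsive=modulated, config=config).label
            n_well += int(label == "well")
            n_unmod += int(label == "unmodulated")
        sd = np.sqrt(p_mod * (1 - p_mod) / n)
        assert abs(n_well / n - p_mod) < 3 * sd
        assert abs(n_unmod / n - (1 - p_mod)) < 3 * sd

    def test_scale_invariance(self, config):
        """Rank-based criterion is invariant to uniform response scaling."""
        base = _curves(lambda q: 1.0 + 0.05 * q + 0.001 * q**2)
        scaled = [
            ResponseCurve(c.cell_id, c.mode, c.fixed_value, c.x, 7.3 * c.y_relative, c.y_count)
            for c in base
        ]
        a = classify_modulation(base, es_responsive=True, config=config)
        b = classify_modulation(scaled, es_responsive=True, config=config)
        assert a.label == b.label and a.rho == b.rho
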