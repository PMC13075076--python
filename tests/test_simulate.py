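"""Generator properties: topographies, determinism, ERD power scaling,
spectral content and study structure."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal

import tonguemi as tm
from tonguemi.io import MIRROR_PAIRS
from tonguemi.simulate import subject_ids


class TestTopographies:
    @pytest.mark.parametrize("command,peak", [
        ("LL", "FC6"), ("CL", "FC6"), ("LR", "FC5"), ("CR", "FC5"),
    ])
    def test_contralateral_peak(self, command, peak, montage):
        t = tm.command_topography(command)
        assert montage.labels[int(np.argmax(t.weights))] == peak

    def test_lateral_weight_ordering(self, montage):
        w = dict(zip(montage.labels, tm.command_topography("LL").weights))
        others = [v for k, v in w.items()
                  if k not in ("FC6", "F4", "AF4")]
        assert w["FC6"] > w["F4"] > w["AF4"] > max(others)

    def test_lr_mirrors_ll(self, montage):
        ll = dict(zip(montage.labels, tm.command_topography("LL").weights))
        lr = dict(zip(montage.labels, tm.command_topography("LR").weights))
        for left, right in MIRROR_PAIRS:
            assert ll[left] == lr[right] and ll[right] == lr[left]

    def test_cheek_dominates_corner_elementwise(self):
        ll = tm.command_topography("LL").weights
        cl = tm.command_topography("CL").weights
        assert np.all(cl >= ll)

    def test_vertical_tasks_bilateral(self, montage):
        for cmd in ("LU", "LD"):
            w = dict(zip(montage.labels,
                         tm.command_topography(cmd).weights))
            assert w["FC5"] == w["FC6"] and w["F3"] == w["F4"]
            assert min(w["FC5"], w["F3"]) >= 0.5

    def test_ld_overlap_knob(self):
        cfg_lo = tm.SimulationConfig(lu_ld_overlap=0.0)
        cfg_hi = tm.SimulationConfig(lu_ld_overlap=1.0)
        lu = tm.command_topography("LU", cfg_hi).weights
        assert np.allclose(tm.command_topography("LD", cfg_hi).weights, lu)
        assert not np.allclose(
            tm.command_topography("LD", cfg_lo).weights, lu)

    def test_unknown_command_rejected(self):
        with pytest.raises(ValueError):
            tm.command_topography("XX")


class TestSubjectProfiles:
    def test_deterministic_given_seed_and_id(self, tiny_config):
        a = tm.make_subject_profile(tiny_config, "S01", 5)
        b = tm.make_subject_profile(tiny_config, "S01", 5)
        np.testing.assert_array_equal(a.alpha_amplitude, b.alpha_amplitude)
        assert a.effect_gain == b.effect_gain
        assert a.rng_seed == b.rng_seed

    def test_distinct_across_subjects(self, tiny_config):
        profiles = [tm.make_subject_profile(tiny_config, f"S{i:02d}", 5)
                    for i in range(1, 16)]
        seeds = {p.rng_seed for p in profiles}
        assert len(seeds) == 15

    def test_zero_variability_degenerates(self):
        cfg = tm.SimulationConfig(effect_gain_sd=0.0,
                                  topography_jitter_sd=0.0,
                                  alpha_amplitude_cv=0.0)
        for sid in ("S01", "S09"):
            p = tm.make_subject_profile(cfg, sid, 1)
            assert p.effect_gain == 1.0
            np.testing.assert_allclose(p.topography_jitter, 1.0)


def _alpha_band_power(seg, fs):
    est = tm.welch_psd(seg, fs)
    return tm.band_power(est, tm.ALPHA)


class TestSimulatedTrials:
    def test_phase_onset_events(self, tiny_config):
        p = tm.make_subject_profile(tiny_config, "S01", 0)
        rec = tm.simulate_trial(p, "LL", tiny_config, seed=0)
        assert rec.events == [(0, "baseline"), (1280, "execution"),
                              (2560, "imagery")]
        assert rec.n_samples == 3840

    def test_null_effect_preserves_alpha_power(self):
        # E = 0: baseline and imagery alpha power match in expectation
        cfg = tm.SimulationConfig(
            nominal_erd_percent={c: 0.0 for c in tm.COMMANDS})
        p = tm.make_subject_profile(cfg, "S01", 2)
        p_b = p_i = 0.0
        for k in range(60):
            rec = tm.simulate_trial(p, "LL", cfg, seed=1000 + k)
            ep = tm.segment_trial(rec)
            p_b += np.mean(_alpha_band_power(ep.baseline, cfg.fs))
            p_i += np.mean(_alpha_band_power(ep.imagery, cfg.fs))
        assert p_i / p_b == pytest.approx(1.0, abs=0.05)

    def test_full_suppression_power_ratio(self):
        # w = 1, g = 1, E = 40 -> imagery/baseline alpha power -> 0.6
        cfg = tm.SimulationConfig(
            nominal_erd_percent={c: 40.0 for c in tm.COMMANDS},
            effect_gain_sd=0.0, topography_jitter_sd=0.0,
            background_scale_mean=0.0, sensor_noise_uv=0.0,
            line_amplitude_mean=0.0)
        p = tm.make_subject_profile(cfg, "S01", 3)
        peak = tm.standard_montage().index("FC6")
        p_b = p_i = 0.0
        for k in range(220):
            rec = tm.simulate_trial(p, "LL", cfg, seed=2000 + k)
            ep = tm.segment_trial(rec)
            p_b += _alpha_band_power(ep.baseline, cfg.fs)[peak]
            p_i += _alpha_band_power(ep.imagery, cfg.fs)[peak]
        assert p_i / p_b == pytest.approx(0.6, abs=0.03)

    def test_trial_determinism(self, tiny_config):
        p = tm.make_subject_profile(tiny_config, "S02", 0)
        a = tm.simulate_trial(p, "CR", tiny_config, seed=9)
        b = tm.simulate_trial(p, "CR", tiny_config, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_excess_erd_clipped_with_warning(self, caplog):
        cfg = tm.SimulationConfig(
            nominal_erd_percent={c: 200.0 for c in tm.COMMANDS},
            effect_gain_sd=0.0)
        p = tm.make_subject_profile(cfg, "S01", 0)
        with caplog.at_level("WARNING"):
            rec = tm.simulate_trial(p, "LL", cfg, seed=0)
        assert np.all(np.isfinite(rec.data))
        assert any("clipped" in r.message for r in caplog.records)


class TestSpectralContent:
    def test_alpha_peak_and_line_in_baseline(self):
        cfg = tm.SimulationConfig()
        p = tm.make_subject_profile(cfg, "S01", 11)
        rec = tm.simulate_trial(p, "LU", cfg, seed=11)
        freqs, psd = signal.welch(rec.data, fs=cfg.fs, nperseg=512)
        mean_psd = psd.mean(axis=0)

        def at(f):
            return mean_psd[np.argmin(np.abs(freqs - f))]

        # alpha bump above the neighbouring 1/f trend
        assert at(11.0) > 5 * 0.5 * (at(7.0) + at(16.0))
        # 50 Hz line above its local floor
        assert at(50.0) > 5 * at(46.0)

    def test_notch_removes_simulated_line(self):
        cfg = tm.SimulationConfig(line_amplitude_mean=5.0,
                                  line_amplitude_cv=0.0)
        p = tm.make_subject_profile(cfg, "S01", 12)
        rec = tm.simulate_trial(p, "LL", cfg, seed=12)
        clean = tm.notch_filter(rec)
        freqs, psd0 = signal.welch(rec.data, fs=cfg.fs, nperseg=512)
        _, psd1 = signal.welch(clean.data, fs=cfg.fs, nperseg=512)
        i50 = np.argmin(np.abs(freqs - 50.0))
        assert psd1[:, i50].mean() < 0.01 * psd0[:, i50].mean()


class TestStudyAssembly:
    def test_design_counts_small(self, tiny_config, tiny_study):
        assert len(tiny_study) == 3 * tiny_config.trials_per_subject
        per_subject = {}
        for rec in tiny_study:
            per_subject.setdefault(rec.subject_id, []).append(rec)
        assert all(len(v) == 24 for v in per_subject.values())
        commands = [r.command for r in tiny_study]
        assert {commands.count(c) for c in tm.COMMANDS} == {12}

    def test_sessions_randomize_command_order(self, tiny_study):
        # seeded permutations: not every session is a strict alternation
        first = [r for r in tiny_study
                 if r.subject_id == "S01" and r.session_id == "P1-sess1"]
        seq = [r.command for r in sorted(first,
                                         key=lambda r: r.trial_index)]
        assert sorted(seq) == ["LL", "LL", "LR", "LR"]

    def test_study_reproducible(self, tiny_config):
        a = tm.simulate_study(tiny_config, seed=7)
        b = tm.simulate_study(tiny_config, seed=7)
        assert len(a) == len(b)
        for ra, rb in zip(a[:5], b[:5]):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_subject_ids_default_count(self):
        assert len(subject_ids(tm.SimulationConfig())) == 15
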