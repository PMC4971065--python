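import numpy as np
import pytest

from microstate_rsn import (
    SimConfig,
    build_regressors,
    make_templates,
    simulate_cohort_truth,
    simulate_eeg,
    simulate_labels,
    simulate_rsn_timecourses,
    sort_components,
)
from microstate_rsn.backfit import Segmentation, run_lengths


class TestMakeTemplates:
    def test_normalization_and_separation(self, montage64):
        tset = make_templates(montage64, K=4, seed=0)
        T = tset.templates
        np.testing.assert_allclose(T.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(T, axis=1), 1.0, rtol=1e-12)
        corr = T @ T.T
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) <= 0.7 + 1e-12)

    def test_determinism(self, montage64):
        a = make_templates(montage64, K=5, seed=42).templates
        b = make_templates(montage64, K=5, seed=42).templates
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_channels_rejected(self, ring8):
        with pytest.raises(ValueError):
            make_templates(ring8, K=8, seed=0)


class TestSimulateLabels:
    def test_mean_run_length_converges(self):
        # 100 ms at 125 Hz -> 12.5 samples; Monte-Carlo over ~1e5 runs
        cfg = SimConfig(
            duration_s=12000.0, K_true=4,
            mean_duration_ms={"control": (100.0,) * 4, "patient": (100.0,) * 4},
        )
        labels = simulate_labels(cfg, "control", seed=1)
        _, lengths, _ = run_lengths(labels)
        assert lengths.size > 9e4
        assert abs(lengths.mean() - 12.5) / 12.5 < 0.02

    def test_sub_sample_duration_rejected(self):
        cfg = SimConfig(
            mean_duration_ms={"control": (100.0, 100.0, 100.0, 5.0),
                              "patient": (100.0,) * 4},
        )
        with pytest.raises(ValueError, match="one sample"):
            simulate_labels(cfg, "control", seed=0)

    def test_two_state_alternation(self):
        cfg = SimConfig(
            K_true=2, duration_s=20.0,
            mean_duration_ms={"control": (80.0, 80.0), "patient": (80.0, 80.0)},
        )
        labels = simulate_labels(cfg, "control", seed=2)
        states, _, _ = run_lengths(labels)
        assert np.all(states[1:] != states[:-1])
        assert set(states.tolist()) == {0, 1}

    def test_configurable_transition_kernel(self):
        P = np.array([[0.0, 1.0, 0.0],
                      [0.0, 0.0, 1.0],
                      [1.0, 0.0, 0.0]])  # deterministic cycle 0->1->2->0
        cfg = SimConfig(
            K_true=3, duration_s=30.0, transition_matrix=P,
            mean_duration_ms={"control": (60.0,) * 3, "patient": (60.0,) * 3},
        )
        labels = simulate_labels(cfg, "control", seed=3)
        states, _, _ = run_lengths(labels)
        expected_next = (states[:-1] + 1) % 3
        np.testing.assert_array_equal(states[1:], expected_next)


class TestSimulateEEG:
    def test_average_reference(self, ring8):
        cfg = SimConfig(n_channels=8, duration_s=5.0, n_subjects_per_group=1)
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=4)
        rec = simulate_eeg(cfg, truth, "c00", seed=5)
        assert np.abs(rec.data.mean(axis=0)).max() < 1e-9

    def test_deterministic_with_seed(self, ring8):
        cfg = SimConfig(n_channels=8, duration_s=2.0, n_subjects_per_group=1)
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=6)
        a = simulate_eeg(cfg, truth, "p00", seed=7).data
        b = simulate_eeg(cfg, truth, "p00", seed=7).data
        np.testing.assert_array_equal(a, b)

    def test_noise_free_peak_topographies(self, ring8):
        from microstate_rsn import compute_gfp, find_gfp_peaks

        cfg = SimConfig(n_channels=8, duration_s=20.0, n_subjects_per_group=1,
                        snr=np.inf)
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=8)
        rec = simulate_eeg(cfg, truth, "p00", seed=9)
        g = find_gfp_peaks(compute_gfp(rec))
        labels = truth.label_sequences["p00"]
        T = truth.templates.templates
        x = rec.data[:, g.peak_indices]
        x = x - x.mean(axis=0)
        u = x / np.linalg.norm(x, axis=0)
        rho = np.abs(np.einsum("cp,pc->p", u, T[labels[g.peak_indices]]))
        np.testing.assert_allclose(rho, 1.0, atol=1e-9)

    def test_snr3_peaks_correlate_with_active_template(self, ring8):
        from microstate_rsn import compute_gfp, find_gfp_peaks

        cfg = SimConfig(n_channels=8, duration_s=60.0, n_subjects_per_group=1)
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=10)
        rec = simulate_eeg(cfg, truth, "p00", seed=11)
        g = find_gfp_peaks(compute_gfp(rec))
        labels = truth.label_sequences["p00"]
        T = truth.templates.templates
        x = rec.data[:, g.peak_indices]
        x = x - x.mean(axis=0)
        u = x / np.linalg.norm(x, axis=0)
        rho = np.abs(np.einsum("cp,pc->p", u, T[labels[g.peak_indices]]))
        assert np.mean(rho >= 0.9) >= 0.95


class TestSimulateRSN:
    def _mini_cfg(self):
        return SimConfig(
            n_channels=8, duration_s=70.0, n_subjects_per_group=1,
            n_volumes=30, n_components=6,
            coupling=np.zeros((4, 6)),
        )

    def test_zero_coupling_gives_null_slopes(self, ring8):
        cfg = self._mini_cfg()
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=12)
        seg = Segmentation(truth.label_sequences["p00"],
                           np.ones(cfg.n_samples), cfg.fs)
        regs = build_regressors(seg, cfg.tr_s, cfg.n_volumes, n_states=4)
        slopes = [
            sort_components(regs, simulate_rsn_timecourses(cfg, truth, "p00",
                                                           seed=100 + s))
            for s in range(50)
        ]
        slopes = np.asarray(slopes)
        mean = slopes.mean(axis=0)
        se = slopes.std(axis=0, ddof=1) / np.sqrt(len(slopes))
        # pure AR(1) noise: every mean slope consistent with zero
        assert np.all(np.abs(mean) < 4.5 * se)

    def test_identity_coupling_noise_free(self, ring8):
        cfg = self._mini_cfg()
        cfg.coupling[0, 2] = 1.0
        cfg.rsn_noise_sd = 1e-12
        truth = simulate_cohort_truth(cfg, montage=ring8, seed=13)
        rsn = simulate_rsn_timecourses(cfg, truth, "p00", seed=14)
        seg = Segmentation(truth.label_sequences["p00"],
                           np.ones(cfg.n_samples), cfg.fs)
        regs = build_regressors(seg, cfg.tr_s, cfg.n_volumes, n_states=4)
        # component 2 equals the microstate-A regressor exactly
        np.testing.assert_allclose(rsn.timecourses[2], regs[0], atol=1e-9)
        slopes = sort_components(regs, rsn)
        assert slopes[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_coupling_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            SimConfig(coupling=np.zeros((2, 3)))


def test_group_duration_signs_follow_configuration(ring8):
    """Patients vs controls differences inherit the configured signs."""
    cfg = SimConfig(n_channels=8, duration_s=240.0, n_subjects_per_group=4)
    truth = simulate_cohort_truth(cfg, montage=ring8, seed=15)
    means = {}
    for grp in ("patient", "control"):
        ids = truth.subjects.table.query("group == @grp")["subject_id"]
        durs = []
        for sid in ids:
            labels = truth.label_sequences[sid]
            seg = Segmentation(labels, np.ones(labels.size), cfg.fs)
            from microstate_rsn import compute_metrics

            durs.append(compute_metrics(seg, K=4).mean_duration_ms)
        means[grp] = np.mean(durs, axis=0)
    diff = means["control"] - means["patient"]
    assert diff[0] > 0      # controls dwell longer in A
    assert diff[1] < 0      # patients dwell longer in B
    assert diff[2] < 0      # patients dwell longer in C
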