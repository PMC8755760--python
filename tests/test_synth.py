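import numpy as np
import pandas as pd
import pytest

from stopthink.behavior import estimate_ssrt_integration, score_sif
from stopthink.dcm import build_model_space
from stopthink.synth import (
    NetworkCoupling,
    ROIDesign,
    RaceModelParams,
    canonical_hrf,
    make_population,
    make_task_inputs,
    simulate_log_evidences,
    simulate_network_timeseries,
    simulate_roi_patterns,
    simulate_roi_timecourse,
    simulate_stop_signal,
    simulate_tnt_recall,
)


class TestPopulation:
    def test_empty_population(self):
        pop = make_population(0, -0.5, seed=1)
        assert pop.n_subjects == 0
        assert pop.true_mean_ssrt.size == 0

    def test_large_sample_hits_target_correlation(self):
        pop = make_population(10000, -0.5, seed=1)
        r = np.corrcoef(pop.true_mean_ssrt, pop.true_sif)[0, 1]
        assert r == pytest.approx(-0.5, abs=0.02)

    def test_small_samples_are_unbiased_over_seeds(self):
        rs = [np.corrcoef(p.true_mean_ssrt, p.true_sif)[0, 1]
              for p in (make_population(24, -0.5, seed=k) for k in range(200))]
        assert np.mean(rs) == pytest.approx(-0.5, abs=0.04)

    def test_seed_reproducibility(self):
        a = make_population(24, -0.5, seed=9)
        b = make_population(24, -0.5, seed=9)
        assert np.array_equal(a.true_mean_ssrt, b.true_mean_ssrt)
        assert np.array_equal(a.true_sif, b.true_sif)

    def test_rejects_invalid_target(self):
        with pytest.raises(ValueError):
            make_population(5, 1.5, seed=0)


class TestStopSignal:
    def test_staircase_holds_respond_rate_near_half(self):
        pop = make_population(8, -0.5, seed=7)
        trials = simulate_stop_signal(pop, n_trials=384, prop_stop=0.32, seed=7)
        for _, sub in trials.groupby("subject"):
            s = estimate_ssrt_integration(sub)
            assert 0.36 <= s.p_respond_stop <= 0.69
            assert abs(s.p_respond_stop - 0.5) <= 0.07

    def test_ssds_are_nonnegative_step_multiples(self):
        pop = make_population(3, -0.5, seed=2)
        trials = simulate_stop_signal(pop, n_trials=192, seed=2)
        ssd = trials.loc[trials["trial_type"] == "stop", "ssd_ms"]
        assert (ssd >= 0).all()
        assert np.allclose(ssd % 50.0, 0.0)

    def test_go_only_table_breaks_ssrt_estimation(self):
        pop = make_population(1, -0.5, seed=3)
        trials = simulate_stop_signal(pop, n_trials=50, prop_stop=1e-9, seed=3)
        assert (trials["trial_type"] == "go").all()
        with pytest.raises(ValueError, match="no stop trials"):
            estimate_ssrt_integration(trials)

    def test_race_assumption_holds_in_expectation(self):
        pop = make_population(12, -0.5, seed=4)
        trials = simulate_stop_signal(pop, n_trials=384, seed=4)
        flags = [estimate_ssrt_integration(sub).race_assumption_ok
                 for _, sub in trials.groupby("subject")]
        assert np.mean(flags) >= 0.9

    def test_determinism_and_param_validation(self):
        pop = make_population(2, -0.5, seed=5)
        a = simulate_stop_signal(pop, n_trials=96, seed=5)
        b = simulate_stop_signal(pop, n_trials=96, seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            RaceModelParams(go_sigma=-1.0)
        with pytest.raises(ValueError):
            simulate_stop_signal(pop, n_trials=0, seed=1)


class TestRecall:
    def test_null_effect_recovers_zero_sif(self):
        sifs = []
        for seed in range(40):
            pop = make_population(8, 0.0, seed=seed, sif_mean=0.0, sif_sd=0.0)
            rec = simulate_tnt_recall(pop, seed=seed)
            sifs += [score_sif(rec[rec["subject"] == s]).sif for s in pop.subjects]
        assert np.mean(sifs) == pytest.approx(0.0, abs=0.01)

    def test_recovers_planted_sif(self):
        means = []
        for seed in range(60):
            pop = make_population(24, 0.0, seed=seed, sif_mean=0.05, sif_sd=0.0)
            rec = simulate_tnt_recall(pop, seed=seed)
            means.append(np.mean([score_sif(rec[rec["subject"] == s]).sif
                                  for s in pop.subjects]))
        assert np.mean(means) == pytest.approx(0.05, abs=0.02)

    def test_full_learning_keeps_every_pair(self):
        pop = make_population(2, -0.5, seed=1)
        rec = simulate_tnt_recall(pop, learning_rate=1.0, seed=1)
        assert rec["learned"].all()

    def test_rejects_impossible_recall_probability(self):
        pop = make_population(2, -0.5, seed=1)
        pop.true_sif[:] = 0.9
        with pytest.raises(ValueError):
            simulate_tnt_recall(pop, baseline_recall=0.5, seed=1)


class TestPatterns:
    def test_determinism_and_shapes(self):
        d = [ROIDesign("r", n_voxels=10, g_shared=1.0, s_specific=1.0)]
        a = simulate_roi_patterns(d, n_subjects=3, seed=11)["r"]
        b = simulate_roi_patterns(d, n_subjects=3, seed=11)["r"]
        assert all(np.array_equal(x.betas, y.betas) for x, y in zip(a, b))
        assert a[0].betas.shape == (8, 4, 10)

    def test_no_decline_means_constant_nothink_signal(self):
        d = [ROIDesign("r", n_voxels=16, g_shared=2.0, s_specific=0.0,
                       decline_rate=1.0, noise_sd=0.0)]
        ps = simulate_roi_patterns(d, n_subjects=1, seed=0)["r"][0]
        nt = ps.betas[:, 2, :]
        assert np.allclose(nt, nt[0])

    def test_decline_shrinks_nothink_signal_geometrically(self):
        d = [ROIDesign("r", n_voxels=16, g_shared=2.0, s_specific=0.0,
                       decline_rate=0.5, noise_sd=0.0)]
        ps = simulate_roi_patterns(d, n_subjects=1, seed=0)["r"][0]
        norms = np.linalg.norm(ps.betas[:, 2, :], axis=1)
        assert np.allclose(norms / norms[0], 0.5 ** np.arange(8))

    def test_rejects_single_voxel(self):
        with pytest.raises(ValueError):
            ROIDesign("r", n_voxels=1)


class TestTimecourses:
    def test_hrf_is_zero_at_onset(self):
        assert canonical_hrf([0.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_sign_shows_in_window(self):
        tc = simulate_roi_timecourse({("M1", "Stop"): -1.0}, n_subjects=24,
                                     noise_sd=0.1, subject_sd=0.1, seed=1)
        window = tc[tc["time_s"].isin([2.0, 4.0, 6.0])]
        assert window["bold"].mean() < 0

    def test_determinism(self):
        kw = dict(n_subjects=3, seed=4)
        a = simulate_roi_timecourse({("M1", "Stop"): 1.0}, **kw)
        b = simulate_roi_timecourse({("M1", "Stop"): 1.0}, **kw)
        pd.testing.assert_frame_equal(a, b)


class TestEvidence:
    def test_planted_family_and_unknown_label(self):
        space = build_model_space()
        ev = simulate_log_evidences(5, space, "preferred", 3.0, seed=0)
        assert ev.log_evidence.shape == (5, 73)
        with pytest.raises(ValueError, match="unknown family"):
            simulate_log_evidences(5, space, "not-a-family", 1.0, seed=0)

    def test_single_subject_matrix(self):
        space = build_model_space()
        ev = simulate_log_evidences(1, space, None, seed=3)
        assert ev.log_evidence.shape == (1, 73)


class TestNetwork:
    def test_determinism(self):
        space = build_model_space()
        m = space.by_id(12)
        a = simulate_network_timeseries(m, n_scans=64, seed=5)
        b = simulate_network_timeseries(m, n_scans=64, seed=5)
        assert np.array_equal(a, b)

    def test_unstable_coupling_rejected(self):
        space = build_model_space()
        with pytest.raises(ValueError, match="unstable"):
            simulate_network_timeseries(space.by_id(0),
                                        coupling=NetworkCoupling(a_self=1.2),
                                        n_scans=32, seed=0)

    def test_undriven_nodes_are_noise_without_coupling(self):
        space = build_model_space()
        c = NetworkCoupling(a_self=0.0, a_intrinsic=0.0, b_mod=0.0,
                            c_drive=1.0, state_noise_sd=0.0, obs_noise_sd=0.01)
        y = simulate_network_timeseries(space.by_id(0), coupling=c,
                                        n_scans=128, seed=2, convolve=False)
        # hippocampus and M1 receive no drive and no coupling
        assert np.std(y[:, 2]) < 0.05
        assert np.std(y[:, 3]) < 0.05
        assert np.std(y[:, 0]) > 0.1  # rDLPFC is driven

    def test_inputs_are_disjoint_boxcars(self):
        u = make_task_inputs(120)
        assert set(u) == {"Stop", "No-Think"}
        assert np.max(u["Stop"] + u["No-Think"]) <= 1.0
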