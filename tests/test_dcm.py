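import numpy as np
import pytest

from stopthink.dcm import (
    EvidenceMatrix,
    NODES,
    build_model_space,
    evidence_proxy_fit,
    family_bms,
    rfx_bms,
    staged_family_comparisons,
)
from stopthink.synth import (
    make_task_inputs,
    simulate_log_evidences,
    simulate_network_timeseries,
)
from stopthink.synth.network import hrf_kernel


@pytest.fixture(scope="module")
def space():
    return build_model_space()


class TestModelSpace:
    def test_counts(self, space):
        assert len(space) == 73
        part = space.family_partitions["direction"]
        assert part["null"] == [0]
        assert all(len(part[d]) == 24
                   for d in ("bidirectional", "top_down", "bottom_up"))

    def test_parallel_bidirectional_subfamily_has_eight_models(self, space):
        sub = space.find(direction="bidirectional", pathway="both")
        assert len(sub) == 8  # 4 interaction variants x 2 target families
        ids = sorted(m.id for m in sub)
        assert ids == [9, 10, 11, 12, 21, 22, 23, 24]

    def test_null_model_is_empty(self, space):
        null = space.by_id(0)
        assert null.edge_set("Stop") == frozenset()
        assert null.edge_set("No-Think") == frozenset()

    def test_no_edges_between_targets(self, space):
        for m in space.models:
            for cond in ("Stop", "No-Think"):
                for s, t in m.edge_set(cond):
                    assert {s, t} != {"hippocampus", "M1"}

    def test_preferred_targets_map_conditions_to_their_regions(self, space):
        m = space.by_id(12)  # parallel, bidirectional interaction, preferred
        stop_targets = {t for s, t in m.edge_set("Stop")} | \
                       {s for s, t in m.edge_set("Stop")}
        nothink_targets = {t for s, t in m.edge_set("No-Think")} | \
                          {s for s, t in m.edge_set("No-Think")}
        assert "M1" in stop_targets and "hippocampus" not in stop_targets
        assert "hippocampus" in nothink_targets and "M1" not in nothink_targets

    def test_direction_controls_edge_orientation(self, space):
        td = space.find(direction="top_down", pathway="both",
                        interaction="none", targets="preferred")[0]
        for s, t in td.edge_set("Stop"):
            assert s in ("rDLPFC", "rVLPFC") and t == "M1"
        bu = space.find(direction="bottom_up", pathway="both",
                        interaction="none", targets="preferred")[0]
        for s, t in bu.edge_set("Stop"):
            assert t in ("rDLPFC", "rVLPFC") and s == "M1"


class TestRfxBMS:
    def test_identical_evidences_split_exceedance(self):
        ev = EvidenceMatrix(np.zeros((10, 2)), [0, 1])
        res = rfx_bms(ev, n_samples=200_000, seed=0)
        assert res.exceedance_prob[0] == pytest.approx(0.5, abs=0.01)
        assert res.expected_prob.sum() == pytest.approx(1.0)

    def test_dominant_model_wins(self):
        log_ev = np.zeros((24, 3))
        log_ev[:, 1] = 5.0
        res = rfx_bms(EvidenceMatrix(log_ev, [0, 1, 2]),
                      n_samples=100_000, seed=0)
        assert res.exceedance_prob[1] > 0.99
        assert np.argmax(res.alpha) == 1

    def test_single_subject_flat_evidences_stay_uniform(self):
        ev = EvidenceMatrix(np.zeros((1, 73)), list(range(73)))
        res = rfx_bms(ev, n_samples=10_000, seed=1)
        assert np.allclose(res.expected_prob, 1 / 73, atol=1e-3)

    def test_single_model_has_unit_exceedance(self):
        ev = EvidenceMatrix(np.zeros((5, 1)), [0])
        res = rfx_bms(ev, n_samples=1000, seed=0)
        assert res.exceedance_prob[0] == 1.0

    def test_subject_wise_evidence_shift_invariance(self):
        rng = np.random.default_rng(0)
        log_ev = rng.normal(size=(8, 4))
        shifted = log_ev + rng.normal(size=(8, 1)) * 10
        a = rfx_bms(EvidenceMatrix(log_ev, [0, 1, 2, 3]), n_samples=50_000, seed=2)
        b = rfx_bms(EvidenceMatrix(shifted, [0, 1, 2, 3]), n_samples=50_000, seed=2)
        assert np.allclose(a.alpha, b.alpha, atol=1e-6)

    def test_variational_matches_exact_posterior_on_small_fixture(self):
        # Exact posterior mean of the model frequencies by enumerating all
        # 3^5 assignment vectors of the Dirichlet-multinomial mixture (the
        # infinite-sample limit of a Gibbs sampler).  The mean-field
        # factorisation is accurate in the weak-evidence regime, so the
        # fixture uses small log-evidence differences.
        from itertools import product

        from scipy.special import gammaln, logsumexp

        rng = np.random.default_rng(7)
        log_ev = rng.normal(scale=0.05, size=(5, 3))
        ev = EvidenceMatrix(log_ev, [0, 1, 2])
        res = rfx_bms(ev, n_samples=10_000, seed=0)
        alpha0 = np.ones(3)
        terms = []
        for m in product(range(3), repeat=5):
            counts = np.bincount(m, minlength=3)
            ll = (sum(log_ev[i, mi] for i, mi in enumerate(m))
                  + gammaln(alpha0.sum()) - gammaln(alpha0.sum() + 5)
                  + np.sum(gammaln(alpha0 + counts) - gammaln(alpha0)))
            terms.append((ll, counts))
        lls = np.array([t[0] for t in terms])
        w = np.exp(lls - logsumexp(lls))
        exact = sum(wi * (alpha0 + c) / (alpha0.sum() + 5)
                    for wi, (_, c) in zip(w, terms))
        tv = 0.5 * np.abs(res.expected_prob - exact).sum()
        assert tv < 0.01

    def test_variational_picks_the_exact_winner_under_strong_evidence(self):
        rng = np.random.default_rng(3)
        log_ev = rng.normal(scale=1.0, size=(5, 3))
        log_ev[:, 2] += 2.0
        res = rfx_bms(EvidenceMatrix(log_ev, [0, 1, 2]),
                      n_samples=50_000, seed=0)
        assert int(np.argmax(res.exceedance_prob)) == 2

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError):
            rfx_bms(EvidenceMatrix(np.array([[0.0, np.inf]]), [0, 1]),
                    n_samples=100)


class TestFamilyBMS:
    def test_equal_families_with_exchangeable_evidence(self, space):
        # identical evidences for every model: the two equal-size target
        # families must split the exceedance mass evenly (up to MC error)
        ev = simulate_log_evidences(12, space, None, noise_sd=0.0, seed=0)
        res = family_bms(ev, space.family_partitions["targets"],
                         n_samples=100_000, seed=0)
        assert res.exceedance_prob[0] == pytest.approx(0.5, abs=0.01)

    def test_planted_family_advantage_wins(self, space):
        ev = simulate_log_evidences(24, space, "preferred", 3.0, seed=1)
        res = family_bms(ev, space.family_partitions["targets"],
                         n_samples=100_000, seed=1)
        ep = dict(zip(res.labels, res.exceedance_prob))
        assert ep["preferred"] > 0.9

    def test_unequal_family_sizes_match_sampling_oracle(self):
        # flat evidences over 6 models, families of size 1, 2, 3
        ev = EvidenceMatrix(np.zeros((4, 6)), list(range(6)))
        partition = {"a": [0], "b": [1, 2], "c": [3, 4, 5]}
        res = family_bms(ev, partition, n_samples=400_000, seed=3)
        # oracle: direct Dirichlet sampling with the same posterior alpha
        rng = np.random.default_rng(12345)
        draws = rng.dirichlet(res.alpha, size=400_000)
        sums = np.column_stack([draws[:, [0]].sum(1), draws[:, [1, 2]].sum(1),
                                draws[:, [3, 4, 5]].sum(1)])
        oracle = np.bincount(np.argmax(sums, axis=1), minlength=3) / 400_000
        assert np.allclose(res.exceedance_prob, oracle, atol=0.01)

    def test_overlapping_partition_rejected(self, space):
        ev = simulate_log_evidences(3, space, None, seed=0)
        with pytest.raises(ValueError, match="overlapping"):
            family_bms(ev, {"a": [1, 2], "b": [2, 3]})


class TestEvidenceProxy:
    def test_null_data_favour_null_model(self, space):
        inputs = make_task_inputs(512)
        h = hrf_kernel()
        best_gap = []
        for seed in range(3):
            y = simulate_network_timeseries(space.by_id(0), inputs=inputs,
                                            n_scans=512, seed=seed)
            evs = [evidence_proxy_fit(y, m, inputs, hrf_kernel=h)
                   for m in space.models]
            best_gap.append(evs[0] - max(evs))
        assert np.mean(best_gap) > -2.0

    def test_relabelling_invariance(self, space):
        # swapping rDLPFC and rVLPFC consistently in data and model space
        # leaves the evidence unchanged
        inputs = make_task_inputs(128)
        m = space.by_id(12)
        y = simulate_network_timeseries(m, inputs=inputs, n_scans=128, seed=0)
        swap = {"rDLPFC": "rVLPFC", "rVLPFC": "rDLPFC",
                "hippocampus": "hippocampus", "M1": "M1"}
        from stopthink.dcm import ModelSpec
        m_sw = ModelSpec(
            id=99, direction=m.direction, pathway=m.pathway,
            interaction=m.interaction, targets=m.targets,
            modulatory_edges={c: frozenset((swap[s], swap[t]) for s, t in e)
                              for c, e in m.modulatory_edges.items()})
        idx = [NODES.index(swap[n]) for n in NODES]
        y_sw = y[:, idx]
        e1 = evidence_proxy_fit(y, m, inputs, hrf_kernel=None)
        e2 = evidence_proxy_fit(y_sw, m_sw, inputs, hrf_kernel=None)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_staged_comparisons_recover_planted_family(self, space):
        inputs = make_task_inputs(512)
        h = hrf_kernel()
        true = space.by_id(12)
        log_ev = np.zeros((8, 73))
        for s in range(8):
            y = simulate_network_timeseries(true, inputs=inputs,
                                            n_scans=512, seed=50 + s)
            for m in space.models:
                log_ev[s, m.id] = evidence_proxy_fit(y, m, inputs, hrf_kernel=h)
        ev = EvidenceMatrix(log_ev, [m.id for m in space.models])
        stages = staged_family_comparisons(ev, space, n_samples=20_000, seed=0)
        direction = dict(zip(stages["direction"].labels,
                             stages["direction"].exceedance_prob))
        targets = dict(zip(stages["targets"].labels,
                           stages["targets"].exceedance_prob))
        assert direction["bidirectional"] > 0.9
        assert targets["preferred"] > 0.9
        assert stages["all_models"].labels[
            int(np.argmax(stages["all_models"].exceedance_prob))] == 12
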