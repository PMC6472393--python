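"""RDM estimation from partial arrangements, pooling, MDS, triad tests."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import alloreach as ar


def right_triangle_trial():
    return ar.ArrangementTrial(("a", "b", "c"),
                               np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]]))


class TestTrialDistances:
    def test_right_triangle(self):
        out = ar.trial_distances(right_triangle_trial())
        got = dict(zip(zip(out["item_a"], out["item_b"]), out["distance"]))
        assert got[("a", "b")] == pytest.approx(3.0)
        assert got[("a", "c")] == pytest.approx(4.0)
        assert got[("b", "c")] == pytest.approx(5.0)

    def test_colocated_pair_zero(self):
        trial = ar.ArrangementTrial(("a", "b", "c"),
                                    np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]))
        out = ar.trial_distances(trial)
        assert out["distance"].min() == 0.0

    def test_random_placements_brute_force(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 5, (10, 2))
        items = tuple(f"i{k}" for k in range(10))
        out = ar.trial_distances(ar.ArrangementTrial(items, pos))
        for (ia, ib, d) in out.itertuples(index=False):
            a, b = items.index(ia), items.index(ib)
            assert d == pytest.approx(np.hypot(*(pos[a] - pos[b])))

    def test_duplicate_item_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ar.ArrangementTrial(("a", "a", "b"), np.zeros((3, 2)))


class TestEstimateRdm:
    def test_single_trial_equals_unit_max_distances(self):
        trial = right_triangle_trial()
        rdm = ar.estimate_rdm([trial])
        expected = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]]) / 5.0
        assert np.allclose(rdm.matrix, expected)
        assert rdm.normalization == "unit-max"

    def test_rescaled_trials_consistent(self):
        """Two exact rescalings of one configuration recover the same RDM."""
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 3, (6, 2))
        items = tuple("abcdef")
        trials = [ar.ArrangementTrial(items, pos),
                  ar.ArrangementTrial(items, 3.7 * pos)]
        rdm = ar.estimate_rdm(trials)
        single = ar.estimate_rdm([trials[0]])
        assert np.allclose(rdm.matrix, single.matrix, atol=1e-9)

    def test_noise_free_recovery(self, semantic_space):
        sessions = ar.simulate_arrangement_session(semantic_space, 24,
                                                   placement_noise=0.0, seed=4)
        rdm = ar.estimate_rdm(sessions)
        latent = squareform(semantic_space.distances(), checks=False)
        r = stats.pearsonr(latent, rdm.condensed())[0]
        assert r > 0.99

    def test_global_rescaling_invariance(self, semantic_space):
        trials = ar.simulate_arrangement_session(semantic_space, 6, 0.2, seed=5)
        scaled = [ar.ArrangementTrial(t.items, np.asarray(t.positions) * 2.5)
                  for t in trials]
        a = ar.estimate_rdm(trials)
        b = ar.estimate_rdm(scaled)
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_recovery_improves_with_trials(self, semantic_space):
        latent = squareform(semantic_space.distances(), checks=False)

        def rho(n_trials):
            trials = ar.simulate_arrangement_session(semantic_space, n_trials,
                                                     placement_noise=1.5, seed=6)
            return stats.spearmanr(latent, ar.estimate_rdm(trials).condensed())[0]

        assert rho(24) > rho(2) - 0.02

    def test_pooled_recovery_from_noisy_sessions(self, semantic_space):
        rdms = [ar.estimate_rdm(ar.simulate_arrangement_session(
            semantic_space, 24, 0.5, seed=100 + s)) for s in range(15)]
        pooled = ar.pool_rdms(rdms)
        latent = squareform(semantic_space.distances(), checks=False)
        rho = stats.spearmanr(latent, pooled.condensed())[0]
        assert rho > 0.9


class TestPoolRdms:
    def test_idempotent_on_identical_rdms(self):
        rdm = ar.estimate_rdm([right_triangle_trial()])
        pooled = ar.pool_rdms([rdm, rdm, rdm])
        assert np.allclose(pooled.matrix, rdm.matrix)

    def test_scale_invariance(self):
        rdm = ar.estimate_rdm([right_triangle_trial()])
        scaled = ar.RDM(rdm.items, rdm.matrix * 7.0, "raw")
        pooled = ar.pool_rdms([rdm, scaled])
        assert np.allclose(pooled.matrix, rdm.matrix)

    def test_pooling_reduces_noise(self, semantic_space):
        latent = semantic_space.distances()
        latent = latent / latent.max()
        rng = np.random.default_rng(7)
        noisy = []
        for _ in range(15):
            noise = np.abs(latent + rng.normal(0, 0.15, latent.shape))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            noisy.append(ar.RDM(semantic_space.items, noise, "raw"))
        pooled = ar.pool_rdms(noisy)
        rms_pooled = np.sqrt(((pooled.matrix / pooled.matrix.max() - latent) ** 2).mean())
        rms_each = np.median([np.sqrt(((r.matrix / r.matrix.max() - latent) ** 2).mean())
                              for r in noisy])
        assert rms_pooled < rms_each

    def test_label_mismatch_rejected(self):
        a = ar.estimate_rdm([right_triangle_trial()])
        b = ar.RDM(("x", "y", "z"), a.matrix, "raw")
        with pytest.raises(ValueError, match="mismatch"):
            ar.pool_rdms([a, b])


class TestMdsEmbed:
    def test_planar_points_embed_exactly(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 3, (12, 2))
        rdm = ar.RDM(tuple(f"i{k}" for k in range(12)),
                     squareform(pdist(pts)), "raw")
        coords, stress = ar.mds_embed(rdm, 2, n_init=8, seed=0)
        assert stress < 1e-3
        assert np.allclose(pdist(coords), pdist(pts), rtol=1e-2, atol=0.05)

    def test_equilateral_triangle_zero_stress(self):
        m = np.ones((3, 3)) - np.eye(3)
        rdm = ar.RDM(("a", "b", "c"), m, "raw")
        _, stress = ar.mds_embed(rdm, 2, seed=1)
        assert stress < 1e-4

    def test_square_matches_exact_embedding(self):
        """Unit square RDM embeds at near-zero stress; distances reproduced."""
        s2 = np.sqrt(2)
        m = np.array([[0, 1, s2, 1], [1, 0, 1, s2], [s2, 1, 0, 1], [1, s2, 1, 0]])
        rdm = ar.RDM(tuple("abcd"), m, "raw")
        coords, stress = ar.mds_embed(rdm, 2, n_init=8, seed=2)
        assert stress < 1e-4
        assert np.allclose(np.sort(pdist(coords)), np.sort(squareform(m, checks=False)),
                           atol=1e-3)

    def test_missing_entries_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        rdm = ar.RDM(("a", "b", "c"), m, "raw")
        with pytest.raises(ValueError, match="missing"):
            ar.mds_embed(rdm)


class TestRandomTriadTest:
    def test_flat_rdm_gives_zero_diff(self):
        m = np.ones((8, 8)) - np.eye(8)
        rdm = ar.RDM(tuple("abcdefgh"), m, "raw")
        out = ar.random_triad_test(rdm, ("a", "b", "c"), n_random=20, seed=0)
        assert out.m_diff == 0.0 and out.t == 0.0

    def test_tight_triad_negative_diff(self, semantic_space):
        rdm = ar.RDM(semantic_space.items,
                     semantic_space.distances() / semantic_space.distances().max(),
                     "unit-max")
        labels = np.asarray(semantic_space.clusters)
        triad = tuple(np.asarray(semantic_space.items)[labels == 0][:3])
        out = ar.random_triad_test(rdm, triad, n_random=1000, seed=1)
        assert out.m_diff < 0 and out.t < 0 and out.p < 0.001

    def test_exhaustive_enumeration_oracle(self):
        """n_random covering the population reproduces brute-force enumeration."""
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (8, 2))
        m = squareform(pdist(pts))
        items = tuple("abcdefgh")
        rdm = ar.RDM(items, m, "raw")
        triad = ("a", "b", "c")
        out = ar.random_triad_test(rdm, triad, n_random=10_000, seed=2)

        tri_mean = (m[0, 1] + m[0, 2] + m[1, 2]) / 3
        rand_means = [
            (m[i, j] + m[i, k] + m[j, k]) / 3
            for i, j, k in itertools.combinations(range(8), 3)
            if {i, j, k} != {0, 1, 2}
        ]
        assert out.n_random == len(rand_means) == 55
        assert out.m_diff == pytest.approx(tri_mean - np.mean(rand_means))
        t_ref, p_ref = stats.ttest_1samp(tri_mean - np.array(rand_means), 0.0)
        assert out.t == pytest.approx(t_ref)
        assert out.p == pytest.approx(p_ref)

    def test_small_item_set_rejected(self):
        rdm = ar.estimate_rdm([right_triangle_trial()])
        with pytest.raises(ValueError):
            ar.random_triad_test(rdm, ("a", "b", "c"))


class TestSelectNextSubset:
    @staticmethod
    def _uniform_rdm(n=6):
        items = tuple(f"i{k}" for k in range(n))
        return ar.RDM(items, np.ones((n, n)) - np.eye(n), "raw")

    def test_forced_choice_lowest_evidence_pair(self):
        rdm = self._uniform_rdm()
        ev = np.full((6, 6), 100.0)
        np.fill_diagonal(ev, 0)
        ev[1, 4] = ev[4, 1] = 0.0
        subset = ar.select_next_subset(rdm, ev, (3, 5), seed=0)
        assert {"i1", "i4"} <= set(subset)
        assert len(subset) == 3

    def test_uniform_evidence_hits_size_bound(self):
        """Every pair equally needy: utility outpaces cost, subset grows to the cap."""
        rdm = self._uniform_rdm()
        ev = np.full((6, 6), 5.0)
        np.fill_diagonal(ev, 0)
        a = ar.select_next_subset(rdm, ev, (3, 5), seed=3)
        assert len(a) == 5
        assert ar.select_next_subset(rdm, ev, (3, 5), seed=3) == a  # seeded ties

    def test_completion_signal_at_ceiling(self):
        rdm = self._uniform_rdm()
        ev = np.full((6, 6), 9.0)
        np.fill_diagonal(ev, 0)
        assert ar.select_next_subset(rdm, ev, (3, 5), evidence_ceiling=8.0) == ()

    def test_first_pair_is_brute_force_argmin(self):
        rng = np.random.default_rng(10)
        rdm = self._uniform_rdm()
        ev = rng.uniform(1, 10, (6, 6))
        ev = (ev + ev.T) / 2
        np.fill_diagonal(ev, 0)
        subset = ar.select_next_subset(rdm, ev, (3, 4), seed=1)
        pairs = list(itertools.combinations(range(6), 2))
        i, j = min(pairs, key=lambda p: ev[p[0], p[1]])
        assert {f"i{i}", f"i{j}"} <= set(subset)


class TestSelectTriads:
    @staticmethod
    def _criterion_rdms():
        """Cluster 0 tight semantically but shape-diverse; cluster 1 the reverse."""
        items = tuple(f"i{k}" for k in range(8))
        sem = np.ones((8, 8)) * 0.8
        sem[:4, :4] = 0.1  # cluster 0 semantically tight
        shape = np.ones((8, 8)) * 0.5
        shape[:4, :4] = 0.9  # ... and shape-diverse
        shape[4:, 4:] = 0.05
        for m in (sem, shape):
            np.fill_diagonal(m, 0)
        return {"no_instruction": ar.RDM(items, sem, "raw"),
                "object": ar.RDM(items, sem.copy(), "raw"),
                "shape": ar.RDM(items, shape, "raw")}

    def test_constructed_winner_ranks_first(self):
        ranked = ar.select_triads(self._criterion_rdms(), lam=1.0)
        assert set(ranked.iloc[0]["triad"]) <= {"i0", "i1", "i2", "i3"}

    def test_lambda_zero_is_semantic_tightness(self):
        rdms = self._criterion_rdms()
        ranked = ar.select_triads(rdms, lam=0.0)
        scores = ranked["score"]
        semantic = [rdms["no_instruction"].pair_mean(t) + rdms["object"].pair_mean(t)
                    for t in ranked["triad"]]
        assert np.allclose(scores, semantic)

    def test_ranking_matches_brute_force(self):
        rdms = self._criterion_rdms()
        ranked = ar.select_triads(rdms, lam=1.3)
        best = ranked.iloc[0]
        for triad in itertools.combinations(rdms["shape"].items, 3):
            score = (rdms["no_instruction"].pair_mean(triad)
                     + rdms["object"].pair_mean(triad)
                     - 1.3 * rdms["shape"].pair_mean(triad))
            assert score >= best["score"] - 1e-12

    def test_missing_criterion_rejected(self):
        rdms = self._criterion_rdms()
        del rdms["shape"]
        with pytest.raises(ValueError, match="shape"):
            ar.select_triads(rdms)
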