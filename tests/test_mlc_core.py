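from itertools import combinations, product

import numpy as np
import pytest

from mlc.mlc_core import (
    PairMoments,
    SampledPairMoments,
    build_pair_moments,
    fit_mlc,
    fit_mlc_global,
    objective,
    objective_grad,
    partition_pairs,
    partition_pairs_global,
    selected_samples,
    welch_t,
)
from mlc.preprocess import center_scale
from mlc.similarity import WeightVector


def brute_force_welch(X, y, w):
    """Enumerate every p-p and p-n pair's weighted similarity and apply
    the two-sample Welch formula with unbiased variances."""
    P = np.flatnonzero(y == 1)
    Q = np.flatnonzero(y == 0)
    spp = [float(np.sum(w * X[i] * X[j])) for i, j in combinations(P, 2)]
    spn = [float(np.sum(w * X[i] * X[j])) for i, j in product(P, Q)]
    mu1, mu2 = np.mean(spp), np.mean(spn)
    v1 = np.var(spp, ddof=1)
    v2 = np.var(spn, ddof=1)
    return (mu1 - mu2) / np.sqrt(v1 / len(spp) + v2 / len(spn))


def random_instance(rng, n_max=12, f_max=6, n_min=5):
    n = int(rng.integers(n_min, n_max + 1))
    f = int(rng.integers(3, f_max + 1))
    X = center_scale(rng.standard_normal((n, f))).values
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, int(rng.integers(3, n - 1)), replace=False)] = 1
    w = rng.uniform(0.0, 2.0, f)
    return X, y, w


class TestPartition:
    def test_forced_counts(self):
        part = partition_pairs(np.array([1, 1, 0]))
        assert (part.n_pp, part.n_pn) == (1, 2)
        part = partition_pairs(np.array([1, 1, 1, 0, 0]))
        assert (part.n_pp, part.n_pn) == (3, 6)

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=30) < 0.4).astype(int)
        part = partition_pairs(y)
        P = np.flatnonzero(y == 1)
        Q = np.flatnonzero(y == 0)
        assert part.n_pp == len(list(combinations(P, 2)))
        assert part.n_pn == len(P) * len(Q)

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            partition_pairs(np.array([1, 0, 0]))
        with pytest.raises(ValueError):
            partition_pairs(np.array([1, 1, 1]))


class TestGlobalPartition:
    def test_shared_and_disjoint_term_sets(self):
        gene_terms = {
            "a": {"T1", "T2"},
            "b": {"T1", "T2"},
            "c": {"T3"},
        }
        pairs = partition_pairs_global(gene_terms, ["a", "b", "c"])
        assert [tuple(p) for p in pairs.pp_pairs] == [(0, 1)]
        assert {tuple(p) for p in pairs.pn_pairs} == {(0, 2), (1, 2)}

    def test_universal_term_ignored(self):
        # "ROOT" on every gene must not make every pair p-p
        gene_terms = {
            "a": {"ROOT", "T1"},
            "b": {"ROOT", "T1"},
            "c": {"ROOT", "T2"},
        }
        pairs = partition_pairs_global(gene_terms, ["a", "b", "c"])
        assert [tuple(p) for p in pairs.pp_pairs] == [(0, 1)]

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        universe = [f"T{j}" for j in range(4)]
        gene_terms = {
            g: {universe[int(j)] for j in rng.choice(4, rng.integers(1, 3), replace=False)}
            for g in genes
        }
        counts = {t: sum(t in ts for ts in gene_terms.values()) for t in universe}
        informative = {t for t, c in counts.items() if c < len(genes)}
        pairs = partition_pairs_global(gene_terms, genes)
        pp = {tuple(p) for p in pairs.pp_pairs}
        for i, j in combinations(range(10), 2):
            shared = (gene_terms[genes[i]] & gene_terms[genes[j]]) & informative
            assert ((i, j) in pp) == bool(shared)


class TestPairMoments:
    def test_hand_computed_three_gene_instance(self):
        # 2 positives + 1 negative over 2 samples: one p-p pair, two p-n pairs
        X = np.array([[1.0, -1.0], [0.5, 2.0], [-1.0, 3.0]])
        y = np.array([1, 1, 0])
        mom = PairMoments(X, partition_pairs(y))
        z01 = X[0] * X[1]
        assert np.allclose(mom.U, z01)
        assert np.allclose(mom.V, X[2] * (X[0] + X[1]))
        assert np.allclose(mom.M_pp, np.outer(z01, z01))
        z02 = X[0] * X[2]
        z12 = X[1] * X[2]
        assert np.allclose(mom.M_pn, np.outer(z02, z02) + np.outer(z12, z12))

    def test_zero_expression_gives_zero_moments(self):
        X = np.zeros((4, 3))
        mom = PairMoments(X, partition_pairs(np.array([1, 1, 0, 0])))
        assert np.allclose(mom.U, 0) and np.allclose(mom.V, 0)
        assert np.allclose(mom.M_pp, 0) and np.allclose(mom.M_pn, 0)

    def test_moment_statistics_match_pair_enumeration(self):
        rng = np.random.default_rng(2)
        X = center_scale(rng.standard_normal((8, 5))).values
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        part = partition_pairs(y)
        mom = PairMoments(X, part)
        P = np.flatnonzero(y == 1)
        Q = np.flatnonzero(y == 0)
        for _ in range(10):
            w = rng.uniform(0, 1, 5)
            spp = [np.sum(w * X[i] * X[j]) for i, j in combinations(P, 2)]
            spn = [np.sum(w * X[i] * X[j]) for i, j in product(P, Q)]
            mu_pp, mu_pn, var_pp, var_pn, _ = mom.stats(w)
            assert mu_pp == pytest.approx(np.mean(spp), abs=1e-12)
            assert mu_pn == pytest.approx(np.mean(spn), abs=1e-12)
            assert var_pp == pytest.approx(np.var(spp, ddof=1), abs=1e-12)
            assert var_pn == pytest.approx(np.var(spn, ddof=1), abs=1e-12)


class TestWelchT:
    def test_equals_brute_force_over_100_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            X, y, w = random_instance(rng)
            mom = PairMoments(X, partition_pairs(y))
            assert welch_t(w, mom) == pytest.approx(
                brute_force_welch(X, y, w), abs=1e-9
            )

    def test_sampled_moments_agree_when_unsubsampled(self):
        rng = np.random.default_rng(4)
        X, y, w = random_instance(rng)
        P = np.flatnonzero(y == 1)
        Q = np.flatnonzero(y == 0)
        pp = np.array(list(combinations(P, 2)))
        pn = np.array([(i, j) for i in P for j in Q])
        sm = SampledPairMoments(X, pp, pn, max_pairs=10**9)
        assert welch_t(w, sm) == pytest.approx(brute_force_welch(X, y, w), abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X, y, w = random_instance(rng)
            mom = PairMoments(X, partition_pairs(y))
            t1 = welch_t(w, mom)
            for c in (0.1, 10.0):
                assert welch_t(c * w, mom) == pytest.approx(t1, abs=1e-9)

    def test_symmetric_labels_give_zero_t(self):
        # positives and negatives drawn from the same two mirrored genes:
        # every p-p and p-n similarity is identical in distribution
        X = np.tile([1.0, -1.0], (6, 1))
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        y = np.array([1, 1, 1, 0, 0, 0])
        mom = PairMoments(X, partition_pairs(y))
        # all pair similarities equal -> degenerate variance, equal means -> 0
        assert welch_t(np.ones(2), mom) == 0.0

    def test_genes_outside_partition_are_ignored(self):
        # rows never referenced by any pair cannot change t (n-n exclusion)
        rng = np.random.default_rng(6)
        X = center_scale(rng.standard_normal((10, 5))).values
        pp = np.array([(0, 1), (0, 2), (1, 2)])
        pn = np.array([(0, 3), (1, 3), (2, 3), (0, 4), (1, 4), (2, 4)])
        w = rng.uniform(0, 1, 5)
        t1 = welch_t(w, SampledPairMoments(X, pp, pn, max_pairs=10**9))
        X2 = X.copy()
        X2[5:] = center_scale(rng.standard_normal((5, 5))).values
        t2 = welch_t(w, SampledPairMoments(X2, pp, pn, max_pairs=10**9))
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestObjective:
    def test_limits(self):
        rng = np.random.default_rng(7)
        X, y, w = random_instance(rng)
        mom = PairMoments(X, partition_pairs(y))
        t = welch_t(w, mom)
        assert objective(w, mom, 1.0 - 1e-12) == pytest.approx(-t, abs=1e-6)
        w_unit = w / w.sum()
        alpha = 0.25
        t_unit = welch_t(w_unit, mom)
        assert objective(w_unit, mom, alpha) == pytest.approx(
            -alpha * t_unit + (1 - alpha), abs=1e-12
        )

    def test_alpha_domain(self):
        rng = np.random.default_rng(8)
        X, y, w = random_instance(rng)
        mom = PairMoments(X, partition_pairs(y))
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="alpha"):
                objective(w, mom, bad)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n, f = 15, 8
            X = center_scale(rng.standard_normal((n, f))).values
            y = np.zeros(n, dtype=int)
            y[:6] = 1
            w = rng.uniform(0.1, 2.0, f)
            mom = PairMoments(X, partition_pairs(y))
            alpha = float(rng.uniform(0.2, 0.999))
            g = objective_grad(w, mom, alpha)
            h = 1e-6
            for m in range(f):
                wp, wm = w.copy(), w.copy()
                wp[m] += h
                wm[m] -= h
                num = (objective(wp, mom, alpha) - objective(wm, mom, alpha)) / (2 * h)
                assert abs(g[m] - num) / max(abs(num), 1e-8) < 1e-5


class TestFit:
    def test_objective_never_increases_along_trace(self):
        rng = np.random.default_rng(10)
        X = center_scale(rng.standard_normal((40, 12))).values
        y = np.zeros(40, dtype=int)
        y[:10] = 1
        model = fit_mlc(X, y, alpha=0.9)
        trace = np.array(model.trace)
        assert np.all(np.diff(trace) <= 1e-8)
        assert model.objective_value <= trace[0] + 1e-12

    def test_informative_samples_get_larger_weights(self, small_sim):
        X = small_sim.scaled()
        term = "T0"
        model = fit_mlc(X, small_sim.labels[term], alpha=0.99, term=term)
        block = small_sim.ground_truth_blocks[term]
        mask = np.zeros(X.n_samples, dtype=bool)
        mask[block] = True
        w = model.weights.w
        assert w[mask].mean() > w[~mask].mean()

    def test_tiny_alpha_drives_weights_to_zero(self):
        rng = np.random.default_rng(11)
        X = center_scale(rng.standard_normal((20, 6))).values
        y = np.zeros(20, dtype=int)
        y[:6] = 1
        model = fit_mlc(X, y, alpha=1e-9)
        assert model.weights.w.sum() < 1e-6

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(12)
        X = center_scale(rng.standard_normal((30, 10))).values
        y = np.zeros(30, dtype=int)
        y[:8] = 1
        m1 = fit_mlc(X, y, alpha=0.95)
        m2 = fit_mlc(X, y, alpha=0.95)
        assert np.array_equal(m1.weights.w, m2.weights.w)


class TestGlobalFit:
    def test_single_term_corpus_matches_term_specific(self):
        rng = np.random.default_rng(13)
        X = center_scale(rng.standard_normal((40, 25))).values
        y = np.zeros(40, dtype=int)
        y[:12] = 1
        genes = [f"g{i}" for i in range(40)]
        gene_terms = {g: ({"T0"} if y[i] else set()) for i, g in enumerate(genes)}
        m_term = fit_mlc(X, y, alpha=0.95)
        m_glob = fit_mlc_global(X, gene_terms, genes, alpha=0.95)
        assert m_glob.welch_t == pytest.approx(m_term.welch_t, rel=1e-2)
        assert np.allclose(m_glob.weights.w, m_term.weights.w, atol=1e-3)

    def test_two_disjoint_groups_elevate_both_blocks(self, small_sim):
        X = small_sim.scaled()
        genes = list(X.gene_ids)
        gene_terms = {
            g: {t for t, y in small_sim.labels.items() if y[i]}
            for i, g in enumerate(genes)
        }
        model = fit_mlc_global(
            X, gene_terms, genes, alpha=0.99, rng=np.random.default_rng(0)
        )
        w = model.weights.w
        mask = np.zeros(X.n_samples, dtype=bool)
        for t in small_sim.labels:
            block_mask = np.zeros(X.n_samples, dtype=bool)
            block_mask[small_sim.ground_truth_blocks[t]] = True
            assert w[block_mask].mean() > w[~mask & ~block_mask].mean()
            mask |= block_mask


class TestSelection:
    def test_all_zero_weights_select_nothing(self):
        wv = WeightVector(w=np.zeros(5))
        assert wv.selected().size == 0

    def test_relative_threshold(self):
        wv = WeightVector(w=np.array([0.0, 1e-12, 0.3]))
        assert wv.selected(eps=1e-8).tolist() == [2]

    def test_selected_matches_thresholding_oracle(self, small_sim):
        X = small_sim.scaled()
        model = fit_mlc(X, small_sim.labels["T1"], alpha=0.9)
        w = model.weights.w
        expected = np.flatnonzero(w > 1e-8 * w.max())
        assert np.array_equal(selected_samples(model, eps=1e-8), expected)
        assert model.n_selected == expected.size

    def test_memory_cap_triggers_sampled_fallback(self):
        rng = np.random.default_rng(14)
        X = center_scale(rng.standard_normal((10, 8))).values
        part = partition_pairs(np.array([1] * 4 + [0] * 6))
        mom = build_pair_moments(X, part, memory_cap_bytes=10)
        assert isinstance(mom, SampledPairMoments)
        exact = build_pair_moments(X, part)
        assert isinstance(exact, PairMoments)
        w = rng.uniform(0, 1, 8)
        # no subsampling actually happened at this size -> statistics agree
        assert welch_t(w, mom) == pytest.approx(welch_t(w, exact), abs=1e-9)
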