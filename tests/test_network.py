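import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tcna
from tcna import GuideGeneSet, NetworkConfig
from tcna.io import CANONICAL_GUIDE_ROLES
from tcna.network import p_from_r, pearson_rows

from conftest import make_matrix


class TestPearson:
    def test_perfect_linear(self):
        res = tcna.pearson([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == 0.0

    def test_perfect_anti_linear(self):
        res = tcna.pearson([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_matches_direct_formula_and_permutation_null(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # independent brute-force product-moment evaluation
        xm, ym = x.mean(), y.mean()
        r_brute = (((x - xm) * (y - ym)).sum()
                   / math.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()))
        res = tcna.pearson(x, y)
        assert res.r == pytest.approx(r_brute, abs=1e-12)
        # exact permutation null over all 5! orderings of y
        r_obs = abs(res.r)
        count = total = 0
        for perm in itertools.permutations(y):
            rp = abs(np.corrcoef(x, perm)[0, 1])
            count += rp >= r_obs - 1e-12
            total += 1
        p_exact = count / total
        # t-approximation at n=5 is crude; require same order of magnitude
        assert res.p_two_tailed == pytest.approx(p_exact, abs=0.1)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.normal(size=13)
            y = rng.normal(size=13)
            res = tcna.pearson(x, y)
            ref_r, ref_p = stats.pearsonr(x, y)
            assert res.r == pytest.approx(ref_r, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(ref_p, rel=1e-9)

    def test_t_stat_identity(self):
        rng = np.random.default_rng(22)
        x, y = rng.normal(size=(2, 10))
        res = tcna.pearson(x, y)
        expected_t = res.r * math.sqrt(res.df) / math.sqrt(1 - res.r ** 2)
        assert res.t_stat == pytest.approx(expected_t)
        assert res.df == 8

    def test_df_override_changes_p_not_r(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(size=(2, 16))
        a = tcna.pearson(x, y)
        b = tcna.pearson(x, y, df_override=11)
        assert a.r == b.r
        assert b.df == 11
        assert a.p_two_tailed != b.p_two_tailed

    def test_zero_variance_is_undefined_not_crash(self):
        res = tcna.pearson([1, 1, 1], [1, 2, 3])
        assert res.undefined
        assert math.isnan(res.r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tcna.pearson([1, 2, 3], [1, 2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=12),
           st.floats(0.1, 10), st.floats(-50, 50))
    def test_symmetry_and_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(len(xs))
        x = np.array(xs)
        y = rng.normal(size=x.size)
        rx = tcna.pearson(x, y)
        if rx.undefined:
            return
        assert tcna.pearson(y, x).r == rx.r
        assert tcna.pearson(a * x + b, y).r == pytest.approx(rx.r, abs=1e-9)
        assert tcna.pearson(-a * x + b, y).r == pytest.approx(-rx.r, abs=1e-9)


class TestThresholdConsistency:
    def test_critical_r_below_065_at_df11(self):
        # independent oracle: invert the t quantile by hand
        t_crit = stats.t.ppf(0.975, 11)
        r_crit = t_crit / math.sqrt(t_crit ** 2 + 11)
        assert tcna.critical_r(0.05, 11) == pytest.approx(r_crit, abs=1e-12)
        assert r_crit < 0.65

    def test_r_above_065_implies_significant_at_df11(self):
        cfg = NetworkConfig(df_override=11)
        t = 0.65 * math.sqrt(11) / math.sqrt(1 - 0.65 ** 2)
        p = 2 * stats.t.sf(t, 11)
        assert p < 0.05
        rng = np.random.default_rng(31)
        for _ in range(200):
            r = rng.uniform(-0.99, 0.99)
            p_r = float(p_from_r(np.array([r]), 11)[0])
            if r > 0.65:
                assert p_r < 0.05


def guide_set_for(matrix):
    roles = list(CANONICAL_GUIDE_ROLES)[:matrix.n_genes]
    return GuideGeneSet(dict(zip(roles, matrix.gene_ids)))


def brute_force_edges(matrix, guides, cfg):
    """Independent reference: scipy pearsonr per pair, loop construction."""
    edges = set()
    roles = guides.roles
    for ra, rb in itertools.combinations(roles, 2):
        x = matrix.profile(guides.entries[ra])
        y = matrix.profile(guides.entries[rb])
        if x.std() == 0 or y.std() == 0:
            continue
        r, _ = stats.pearsonr(x, y)
        df = cfg.df_override or (len(x) - 2)
        if abs(r) < 1:
            t = r * math.sqrt(df) / math.sqrt(1 - r * r)
            p = 2 * stats.t.sf(abs(t), df)
        else:
            p = 0.0
        if r > cfg.r_min and p < cfg.p_max:
            edges.add(frozenset((ra, rb)))
    return edges


class TestBuildGuideNetwork:
    def test_identical_profiles_give_complete_graph(self, full_guides,
                                                    guide_matrix_identical):
        net = tcna.build_guide_network(guide_matrix_identical, full_guides)
        assert net.n_edges == 15 * 14 // 2
        assert all(d == 14 for d in net.degree.values())

    def test_missing_guide_is_hard_error(self, full_guides, small_matrix):
        with pytest.raises(KeyError, match="PAL1"):
            tcna.build_guide_network(small_matrix, full_guides)

    def test_independent_profiles_yield_few_edges(self):
        # expected edges ~ C(15,2) * P[r > 0.65 & P < .05] under the null
        n_pairs = 15 * 14 // 2
        df = 11
        t_at = 0.65 * math.sqrt(df) / math.sqrt(1 - 0.65 ** 2)
        p_tail = float(stats.t.sf(t_at, df))  # one-sided: positive edges only
        expected = n_pairs * p_tail
        counts = []
        cfg = NetworkConfig(df_override=11)
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            m = make_matrix(np.exp(rng.normal(3, 1, size=(15, 13))))
            g = guide_set_for(m)
            counts.append(tcna.build_guide_network(m, g, cfg).n_edges)
        mean = np.mean(counts)
        se = math.sqrt(expected / 40) * 3 + 0.5
        assert abs(mean - expected) < max(3 * se, 1.0)

    def test_planted_module_edges_only_within_module(self):
        from tcna.simulate import PopulationSimConfig, simulate_population

        anth = ("PAL1", "PAL2", "C4H", "4CL", "CHS1", "CHS2", "CHI", "F3H",
                "DFR", "ANS", "UFGT")
        indep = tuple(r for r in CANONICAL_GUIDE_ROLES if r not in anth)
        trials = 20
        stray = module_edges = dense_trials = 0
        n_cross = 11 * 4 + 4 * 3 // 2  # pairs touching an independent role
        for seed in range(trials):
            cfg = PopulationSimConfig(guide_module_rho=0.9,
                                      independent_roles=indep,
                                      planted_tfs=(), n_background=0,
                                      seed=seed)
            m, truth = simulate_population(cfg)
            # log scale: raw lognormal RPKM has a heavier-tailed null
            net = tcna.build_guide_network(
                m, truth.guides, NetworkConfig(transform="log2p1"))
            in_mod = [e.gene_a in anth and e.gene_b in anth
                      for e in net.edges]
            module_edges += sum(in_mod)
            stray += len(in_mod) - sum(in_mod)
            dense_trials += all(net.degree[r] >= 3 for r in anth)
        # stray edges touch an independent role only through the null tail
        assert stray / (trials * n_cross) < 0.02
        # the planted module is saturated: nearly every within-module pair
        assert module_edges / (trials * 11 * 10 // 2) > 0.9
        assert dense_trials >= trials * 0.9

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(41)
        m = make_matrix(np.exp(rng.normal(3, 1, size=(8, 10))))
        g = guide_set_for(m)
        loose = tcna.build_guide_network(m, g, NetworkConfig(r_min=0.3,
                                                             p_max=0.3))
        tight = tcna.build_guide_network(m, g, NetworkConfig(r_min=0.65,
                                                             p_max=0.05))
        loose_pairs = {frozenset((e.gene_a, e.gene_b)) for e in loose.edges}
        tight_pairs = {frozenset((e.gene_a, e.gene_b)) for e in tight.edges}
        assert tight_pairs <= loose_pairs
        assert all(tight.degree[n] <= loose.degree[n] for n in tight.nodes)

    def test_matches_brute_force_on_small_matrices(self):
        cfg = NetworkConfig()
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n_genes = rng.integers(3, 7)
            n_samples = rng.integers(4, 9)
            m = make_matrix(rng.integers(0, 20, size=(n_genes, n_samples))
                            .astype(float))
            g = guide_set_for(m)
            net = tcna.build_guide_network(m, g, cfg)
            ours = {frozenset((e.gene_a, e.gene_b)) for e in net.edges}
            assert ours == brute_force_edges(m, g, cfg)


class TestCorrelateToGuides:
    def test_identical_to_chs1_is_positive_r1(self, full_guides,
                                              guide_matrix_identical):
        m = guide_matrix_identical
        data = m.data.copy()
        rng = np.random.default_rng(51)
        # decorrelate the other guides so only CHS1 matches
        for gid in m.gene_ids:
            if gid != "gene_CHS1":
                data.loc[gid] = np.exp(rng.normal(3, 1, size=m.n_samples))
        data.loc["cand"] = data.loc["gene_CHS1"] * 2.0
        m2 = make_matrix(data.to_numpy(), gene_ids=list(data.index),
                         sample_ids=m.sample_ids)
        edges = tcna.correlate_to_guides(m2, full_guides, "cand")
        assert edges["CHS1"].positive
        assert edges["CHS1"].result.r == pytest.approx(1.0)

    def test_constant_candidate_all_undefined(self, full_guides,
                                              guide_matrix_identical):
        m = guide_matrix_identical
        data = m.data.copy()
        data.loc["flat"] = 7.0
        m2 = make_matrix(data.to_numpy(), gene_ids=list(data.index),
                         sample_ids=m.sample_ids)
        edges = tcna.correlate_to_guides(m2, full_guides, "flat")
        assert all(e.result.undefined for e in edges.values())
        assert not any(e.positive for e in edges.values())

    def test_planted_links_recovered_across_seeds(self):
        from tcna.simulate import (PlantedTF, PopulationSimConfig,
                                   simulate_population)

        target = ("PAL2", "4CL", "CHS1", "CHS2", "F3H")
        ok = 0
        trials = 40
        for seed in range(trials):
            cfg = PopulationSimConfig(
                n_samples=16, guide_module_rho=0.9,
                planted_tfs=(PlantedTF(target, 0.95),),
                n_background=0, seed=seed)
            m, truth = simulate_population(cfg)
            tf = truth.planted_tf_ids[0]
            edges = tcna.correlate_to_guides(m, truth.guides, tf)
            if all(edges[r].positive for r in target):
                ok += 1
        assert ok >= trials * 0.95


class TestVectorisedHelpers:
    def test_pearson_rows_agrees_with_scalar_path(self):
        rng = np.random.default_rng(61)
        X = rng.normal(size=(4, 9))
        Y = rng.normal(size=(3, 9))
        R = pearson_rows(X, Y)
        for i in range(4):
            for j in range(3):
                assert R[i, j] == pytest.approx(
                    tcna.pearson(X[i], Y[j]).r, abs=1e-12)

    def test_p_from_r_matches_scalar_path(self):
        rng = np.random.default_rng(62)
        r = rng.uniform(-0.99, 0.99, size=20)
        p = p_from_r(r, 11)
        for ri, pi in zip(r, p):
            t = ri * math.sqrt(11) / math.sqrt(1 - ri * ri)
            assert pi == pytest.approx(2 * stats.t.sf(abs(t), 11), rel=1e-9)


def test_bh_adjustment_is_monotone_and_bounded():
    from tcna.network import benjamini_hochberg

    rng = np.random.default_rng(63)
    p = rng.uniform(size=30)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
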