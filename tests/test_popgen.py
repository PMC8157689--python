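"""Diversity/differentiation estimators against hand-computed oracles."""

import numpy as np
import pytest

from popadapt import SimConfig
from popadapt.popgen import (
    amova,
    amova_from_ss,
    heterozygosities,
    nucleotide_diversity,
    pairwise_fst,
    pca,
    weir_cockerham_components,
    weir_cockerham_fst,
)
from popadapt.simulate import simulate_genotypes

from conftest import make_genotype_matrix


class TestNucleotideDiversity:
    def test_monomorphic_window_is_zero(self):
        G = make_genotype_matrix(np.zeros((4, 3)) + 2.0)
        pi = nucleotide_diversity(G, np.array(["A"] * 4))
        assert pi["A"] == 0.0

    def test_single_snp_four_copies_oracle(self):
        # 2 ref / 2 alt among 4 copies: mean pairwise difference = 4/6 = 2/3
        g = np.array([[0.0], [2.0]])
        G = make_genotype_matrix(g)
        pi = nucleotide_diversity(G, np.array(["A", "A"]), window_len=1000)
        assert pi["A"] == pytest.approx((2.0 / 3.0) / 1000.0, abs=1e-12)

    def test_window_length_scaling(self):
        g = np.array([[0.0], [2.0]])
        G = make_genotype_matrix(g)
        pops = np.array(["A", "A"])
        pi1 = nucleotide_diversity(G, pops, window_len=1000)["A"]
        pi2 = nucleotide_diversity(G, pops, window_len=2000)["A"]
        assert pi2 == pytest.approx(pi1 / 2.0)

    def test_invariant_to_locus_and_sample_order(self):
        cfg = SimConfig(n_pops=2, n_ind_per_pop=[8, 8], n_loci=100, seed=2)
        G, t = simulate_genotypes(cfg)
        pi = nucleotide_diversity(G, t.pop_membership)
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(G.n_individuals)
        G2 = G.take_samples(perm_s)
        pi2 = nucleotide_diversity(G2, t.pop_membership[perm_s])
        assert pi["P01"] == pytest.approx(pi2["P01"], abs=1e-15)

    def test_uncallable_population_warns(self):
        g = np.array([[np.nan], [0.0]])
        G = make_genotype_matrix(g)
        with pytest.warns(UserWarning):
            pi = nucleotide_diversity(G, np.array(["A", "B"]))
        assert np.isnan(pi["A"])


class TestHeterozygosities:
    def test_two_heterozygotes_hand_case(self):
        # both individuals Aa: H_O=1; n=4 copies, p=1/2 -> H_E=(4/3)(1/2)=2/3
        g = np.array([[1.0, 1.0], [1.0, 1.0]])
        # add a second "population" so the total dataset is polymorphic
        G = make_genotype_matrix(g)
        res = heterozygosities(G, np.array(["A", "A"]))
        row = res.table.loc["A"]
        assert row["Ho"] == pytest.approx(1.0)
        assert row["He"] == pytest.approx(2.0 / 3.0)
        assert row["Fis"] == pytest.approx(-0.5)

    def test_hwe_simulation_fis_near_zero(self, hwe_matrix):
        res = heterozygosities(hwe_matrix, np.array(["A"] * 30))
        assert abs(res.table.loc["A", "Fis"]) < 0.02

    def test_all_homozygous_population(self):
        # half AA / half aa: H_O = 0, H_E > 0 -> F_IS = 1
        g = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0], [2.0, 2.0]])
        res = heterozygosities(make_genotype_matrix(g), np.array(["A"] * 4))
        assert res.table.loc["A", "Ho"] == 0.0
        assert res.table.loc["A", "Fis"] == pytest.approx(1.0)


def _wc_oracle_two_pops(g1, g2):
    """Independent direct coding of the Weir & Cockerham (1984) equations
    for two populations at one locus, from the genotype tables."""
    stats = []
    for g in (g1, g2):
        g = np.asarray(g, float)
        n = len(g)
        p = g.sum() / (2 * n)
        h = np.mean(g == 1.0)
        stats.append((n, p, h))
    r = 2
    (n1, p1, h1), (n2, p2, h2) = stats
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_identical_tables_give_nonpositive_theta(self):
        rng = np.random.default_rng(3)
        block = rng.binomial(2, 0.4, (10, 50)).astype(float)
        G = make_genotype_matrix(np.vstack([block, block]))
        pops = np.array(["A"] * 10 + ["B"] * 10)
        assert weir_cockerham_fst(G, pops) <= 0.0

    def test_fixed_difference_gives_one(self):
        g = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2.0)])
        G = make_genotype_matrix(g)
        pops = np.array(["A"] * 10 + ["B"] * 10)
        assert weir_cockerham_fst(G, pops) == pytest.approx(1.0)

    def test_against_independent_oracle(self):
        """HWE samples at p=0.1 vs 0.9 equal the hand-coded W&C components."""
        rng = np.random.default_rng(5)
        g1 = rng.binomial(2, 0.1, (10, 1)).astype(float)
        g2 = rng.binomial(2, 0.9, (10, 1)).astype(float)
        G = make_genotype_matrix(np.vstack([g1, g2]))
        pops = np.array(["A"] * 10 + ["B"] * 10)
        a, b, c = weir_cockerham_components(G, pops)
        ao, bo, co = _wc_oracle_two_pops(g1[:, 0], g2[:, 0])
        assert a[0] == pytest.approx(ao, abs=1e-12)
        assert b[0] == pytest.approx(bo, abs=1e-12)
        assert c[0] == pytest.approx(co, abs=1e-12)

    def test_merged_identical_halves_near_zero_and_monotone(self):
        thetas = []
        for F in (0.05, 0.15, 0.3):
            cfg = SimConfig(n_pops=2, n_ind_per_pop=[20, 20], n_loci=1000,
                            fst_target=F, seed=6)
            G, t = simulate_genotypes(cfg)
            thetas.append(weir_cockerham_fst(G, t.pop_membership))
        assert thetas[0] < thetas[1] < thetas[2]
        # split one panmictic sample in two: theta ~ 0
        rng = np.random.default_rng(7)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 500), (40, 500)).astype(float)
        G = make_genotype_matrix(g)
        pops = np.array(["A"] * 20 + ["B"] * 20)
        assert abs(weir_cockerham_fst(G, pops)) < 0.01

    def test_pairwise_permutation_p_detects_structure(self):
        cfg = SimConfig(n_pops=3, n_ind_per_pop=[10] * 3, n_loci=300,
                        fst_target=0.2, seed=8)
        G, t = simulate_genotypes(cfg)
        res = pairwise_fst(G, t.pop_membership, n_perm=99, seed=1)
        assert np.allclose(np.diag(res.theta.to_numpy()), 0.0)
        assert res.theta.equals(res.theta.T)
        assert (res.p_values.to_numpy()[np.triu_indices(3, 1)] <= 0.05).all()


class TestAmova:
    def test_identical_clones_have_no_among_variance(self):
        """Identical populations: the among-population SS is exactly zero, so
        the unbiased Va estimate is non-positive (exactly 0 for homozygous
        clones, where no variance exists at any level)."""
        hom = np.tile(np.array([0.0, 2.0, 2.0, 0.0]), (6, 1))
        res = amova(make_genotype_matrix(hom),
                    np.array(["A", "A", "B", "B", "C", "C"]), n_perm=0)
        assert res.ss_among == pytest.approx(0.0, abs=1e-9)
        assert res.va == pytest.approx(0.0, abs=1e-12)
        assert res.pct_among == pytest.approx(0.0, abs=1e-9)
        het = np.tile(np.array([0.0, 1.0, 2.0, 1.0]), (6, 1))
        res = amova(make_genotype_matrix(het),
                    np.array(["A", "A", "B", "B", "C", "C"]), n_perm=0)
        assert res.ss_among == pytest.approx(0.0, abs=1e-9)
        assert res.va <= 0.0
        assert res.pct_among <= 0.0

    def test_n0_closed_form_for_study_design(self):
        copies = [24, 24, 16, 24, 22, 24, 24, 24, 24, 10]
        res = amova_from_ss(1.0, 1.0, 9, 206, copies)
        assert res.n0 == pytest.approx((216 - 4872 / 216) / 9, abs=1e-12)
        assert res.n0 == pytest.approx(21.4938, abs=1e-4)

    def test_inversion_contrived_va_equals_one(self):
        # choose SS so that (MSA - MSW)/n0 = 1 exactly
        copies = [10.0, 10.0, 10.0]
        n0 = (30 - 300 / 30) / 2.0  # = 10
        ss_within, df_within = 40.0, 27.0
        msw = ss_within / df_within
        df_among = 2.0
        ss_among = (n0 * 1.0 + msw) * df_among
        res = amova_from_ss(ss_among, ss_within, df_among, df_within, copies)
        assert res.va == pytest.approx(1.0, abs=1e-12)

    def test_self_consistency_with_internal_ss(self):
        cfg = SimConfig(n_pops=4, n_ind_per_pop=[8] * 4, n_loci=200,
                        fst_target=0.15, seed=9)
        G, t = simulate_genotypes(cfg)
        res = amova(G, t.pop_membership, n_perm=0)
        res2 = amova_from_ss(res.ss_among, res.ss_within, res.df_among,
                             res.df_within, res.copies_per_pop)
        assert res.phi_st == pytest.approx(res2.phi_st, abs=1e-12)
        assert res.va == pytest.approx(res2.va, abs=1e-12)

    def test_permutation_p_uniform_under_null(self):
        """Phi_ST permutation p-values are uniform when labels carry no
        structure (50 replicates, KS test)."""
        from scipy import stats

        cfg = SimConfig(n_pops=6, n_ind_per_pop=[6] * 6, n_loci=100,
                        fst_target=0.1, seed=2)
        G, t = simulate_genotypes(cfg)
        ps = []
        for s in range(50):
            rng = np.random.default_rng(s)
            labels = rng.permutation(t.pop_membership)
            ps.append(amova(G, labels, n_perm=60, seed=s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_phi_matches_wc_theta_roughly(self):
        cfg = SimConfig(n_pops=5, n_ind_per_pop=[10] * 5, n_loci=500,
                        fst_target=0.25, seed=3)
        G, t = simulate_genotypes(cfg)
        res = amova(G, t.pop_membership, n_perm=0)
        theta = weir_cockerham_fst(G, t.pop_membership)
        assert res.phi_st == pytest.approx(theta, abs=0.03)


class TestPca:
    def test_separates_two_populations(self):
        from sklearn.metrics import silhouette_score

        cfg = SimConfig(n_pops=2, n_ind_per_pop=[15, 15], n_loci=500,
                        fst_target=0.3, seed=4)
        G, t = simulate_genotypes(cfg)
        scores, fracs = pca(G, n_components=2)
        labels = (t.pop_membership == "P01").astype(int)
        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_scores_orthogonal_and_fractions_bounded(self):
        cfg = SimConfig(n_pops=3, n_ind_per_pop=[8] * 3, n_loci=300, seed=5)
        G, _ = simulate_genotypes(cfg)
        scores, fracs = pca(G, n_components=4)
        assert abs(np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]) < 1e-8
        assert fracs.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(fracs) <= 1e-12)
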