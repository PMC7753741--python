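import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parallodrome import popgen as pg
from parallodrome.io import MISSING

from conftest import make_matrix, make_meta


def tetra_meta(n, population="pop1", region="NT", ecotype="foothill"):
    return make_meta([(f"t{i}", population, region, ecotype, 4)
                      for i in range(n)])


def diploid_meta(n, population="pop1", region="NT", ecotype="foothill"):
    return make_meta([(f"d{i}", population, region, ecotype, 2)
                      for i in range(n)])


class TestSubsampleAlleles:
    def test_boundary_dosages(self):
        G = make_matrix(tetra_meta(1), [[0, 4]])
        out = pg.subsample_alleles(G, seed=0)
        assert out.dosages.tolist() == [[0, 2]]
        assert out.samples["ploidy"].tolist() == [2]

    def test_hypergeometric_distribution(self):
        """Tetraploid dosage 2 -> P(diploid dosage 1) = 4/6."""
        G = make_matrix(tetra_meta(1), [[2] * 10_000])
        out = pg.subsample_alleles(G, seed=1)
        frac = (out.dosages[0] == 1).mean()
        se = np.sqrt(4 / 6 * 2 / 6 / 10_000)
        assert abs(frac - 4 / 6) < 3 * se

    def test_diploid_pass_through(self):
        G = make_matrix(diploid_meta(2), [[0, 1], [2, MISSING]])
        out = pg.subsample_alleles(G, seed=2)
        np.testing.assert_array_equal(out.dosages, G.dosages)

    def test_preserves_expected_frequency(self):
        """Mean reduced frequency over seeds matches the tetraploid
        frequency within 3 SE."""
        G = make_matrix(tetra_meta(4), [[1], [2], [3], [4]])
        p_full = 10 / 16
        means = [pg.subsample_alleles(G, seed=s).dosages[:, 0].sum() / 8
                 for s in range(1000)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - p_full) < 3 * se

    def test_target_above_ploidy_rejected(self):
        G = make_matrix(diploid_meta(1), [[1]])
        with pytest.raises(ValueError, match="target_ploidy"):
            pg.subsample_alleles(G, target_ploidy=4)


class TestFiltering:
    def test_thinning_keeps_one_snp_per_window(self):
        G = make_matrix(diploid_meta(2), [[0, 1, 1], [1, 1, 0]],
                        positions=[10, 20, 30])
        out = pg.ld_thin(G, window_bp=150_000, seed=0)
        assert out.n_loci == 1

    def test_thinning_idempotent(self):
        rng = np.random.default_rng(0)
        G = make_matrix(diploid_meta(3), rng.integers(0, 3, size=(3, 40)),
                        positions=rng.choice(10**7, size=40, replace=False) + 1)
        once = pg.ld_thin(G, seed=5)
        twice = pg.ld_thin(once, seed=5)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_singleton_removal(self):
        """Minor-allele count of exactly 1 (derived or ancestral) drops."""
        G = make_matrix(diploid_meta(3),
                        [[1, 2, 0, 2], [0, 2, 1, 2], [0, 2, 1, 1]])
        out = pg.remove_singletons(G)
        # locus 0: derived 1 (drop); locus 1: derived 6 = fixed (keep);
        # locus 2: derived 2 (keep); locus 3: ancestral singleton (drop)
        assert out.loci["pos"].tolist() == [G.loci["pos"][1], G.loci["pos"][2]]


class TestDiversity:
    def test_monomorphic_locus_has_zero_pi(self):
        G = make_matrix(diploid_meta(3), [[0], [0], [0]])
        assert pg.nucleotide_diversity(G, "pop1") == 0.0

    def test_half_frequency_locus(self):
        """n = 4 lineages with derived total 2: pi = (4/3) * 0.5 = 2/3."""
        G = make_matrix(diploid_meta(2), [[1], [1]])
        assert pg.nucleotide_diversity(G, "pop1") == pytest.approx(2 / 3)

    def test_pi_equals_exhaustive_pairs(self):
        """Matches brute-force mean pairwise difference over all lineage
        pairs on 100 random mixed-ploidy matrices, to 1e-10."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_dip = rng.integers(1, 4)
            n_tet = rng.integers(1, 4)
            meta = make_meta(
                [(f"d{i}", "p", "NT", "foothill", 2) for i in range(n_dip)]
                + [(f"t{i}", "p", "NT", "foothill", 4) for i in range(n_tet)])
            n_loci = rng.integers(1, 6)
            ploidy = meta["ploidy"].to_numpy()
            dos = np.array([rng.integers(0, p + 1, size=n_loci) for p in ploidy])
            G = make_matrix(meta, dos)
            per_locus = []
            for l in range(n_loci):
                alleles = np.concatenate([
                    [1] * dos[i, l] + [0] * (ploidy[i] - dos[i, l])
                    for i in range(len(meta))
                ])
                diffs = [alleles[i] != alleles[j]
                         for i in range(len(alleles))
                         for j in range(i + 1, len(alleles))]
                per_locus.append(np.mean(diffs))
            assert pg.nucleotide_diversity(G, "p") == pytest.approx(
                np.mean(per_locus), abs=1e-10)

    def test_too_few_lineages_rejected(self):
        G = make_matrix(diploid_meta(1), [[1]])
        with pytest.raises(ValueError, match="lineages"):
            pg.nucleotide_diversity(G, "nope")


class TestTajimasD:
    def test_no_segregating_sites_is_missing(self):
        # one monomorphic locus, one fixed derived (4/4): S = 0
        G = make_matrix(diploid_meta(2), [[0, 2], [0, 2]])
        assert np.isnan(pg.tajimas_d(G, "pop1"))

    def test_hand_computed_case(self):
        """n = 4 lineages, S = 2 with derived counts (1, 2):
        pi_total = 7/6, theta_w = 2/a1, D = 0.5915801399 (computed by an
        independent constants-from-scratch reference script)."""
        G = make_matrix(diploid_meta(2), [[1, 2], [0, 0]])
        assert pg.tajimas_d(G, "pop1") == pytest.approx(0.5915801398995593,
                                                        abs=1e-10)

    def test_agrees_with_reference_implementation(self):
        """pi, theta_w and D match an independently coded reference on
        100 random matrices to 1e-10."""
        def reference_d(dos, ploidy):
            n = int(ploidy.sum())
            d = dos.sum(axis=0)
            seg = (d > 0) & (d < n)
            S = int(seg.sum())
            if S == 0:
                return None
            pi = sum(dd * (n - dd) / (n * (n - 1) / 2) for dd in d[seg])
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1, e2 = c1 / a1, c2 / (a1**2 + a2)
            return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            n_ind = rng.integers(2, 6)
            p = int(rng.choice([2, 4]))
            meta = make_meta([(f"s{i}", "p", "NT", "foothill", p)
                              for i in range(n_ind)])
            dos = rng.integers(0, p + 1, size=(n_ind, rng.integers(2, 8)))
            expect = reference_d(dos, meta["ploidy"].to_numpy())
            if expect is None or n_ind * p < 4:
                continue
            G = make_matrix(meta, dos)
            assert pg.tajimas_d(G, "p") == pytest.approx(expect, abs=1e-10)
            checked += 1


class TestHudsonFst:
    def test_identical_frequencies_near_zero(self):
        """Two large samples drawn from the same allele frequencies."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=2000)
        meta = make_meta([(f"a{i}", "A", "NT", "foothill", 2) for i in range(50)]
                         + [(f"b{i}", "B", "NT", "alpine", 2) for i in range(50)])
        dos = rng.binomial(2, p[None, :].repeat(100, axis=0))
        G = make_matrix(meta, dos)
        assert abs(pg.hudson_fst(G, "A", "B")) < 0.01

    def test_fixed_differences_give_one(self):
        meta = make_meta([("a1", "A", "NT", "foothill", 2),
                          ("a2", "A", "NT", "foothill", 2),
                          ("b1", "B", "NT", "alpine", 4)])
        G = make_matrix(meta, [[2, 0], [2, 0], [0, 4]])
        assert pg.hudson_fst(G, "A", "B") == pytest.approx(1.0)

    def test_invariant_to_locus_order_and_relabeling(self):
        rng = np.random.default_rng(4)
        meta = make_meta([(f"a{i}", "A", "NT", "foothill", 2) for i in range(4)]
                         + [(f"b{i}", "B", "NT", "alpine", 4) for i in range(3)])
        dos = np.array([rng.integers(0, p + 1, size=30)
                        for p in meta["ploidy"]])
        G = make_matrix(meta, dos)
        f0 = pg.hudson_fst(G, "A", "B")
        perm = rng.permutation(30)
        f1 = pg.hudson_fst(G.take_loci(perm), "A", "B")
        within = np.concatenate([rng.permutation(4), 4 + rng.permutation(3)])
        f2 = pg.hudson_fst(G.take_samples(within), "A", "B")
        assert f0 == pytest.approx(f1, abs=1e-12)
        assert f0 == pytest.approx(f2, abs=1e-12)

    def test_fst_matrix_symmetric(self):
        rng = np.random.default_rng(5)
        meta = make_meta([(f"s{i}", f"p{i % 3}", "NT", "foothill", 2)
                          for i in range(9)])
        G = make_matrix(meta, rng.integers(0, 3, size=(9, 50)))
        M = pg.fst_matrix(G, ["p0", "p1", "p2"])
        np.testing.assert_allclose(M.to_numpy(), M.to_numpy().T)
        assert np.allclose(np.diag(M), 0)


#: printed 8-individual x 10-locus fixture for the AMOVA oracle: three
#: populations in two groups, mixed ploidy
AMOVA_META = make_meta([
    ("i1", "p1", "G1", "foothill", 2),
    ("i2", "p1", "G1", "foothill", 2),
    ("i3", "p2", "G1", "alpine", 2),
    ("i4", "p2", "G1", "alpine", 2),
    ("i5", "p2", "G1", "alpine", 2),
    ("i6", "p3", "G2", "foothill", 4),
    ("i7", "p3", "G2", "foothill", 4),
    ("i8", "p3", "G2", "foothill", 4),
])
AMOVA_DOSAGES = np.array([
    [1, 0, 2, 1, 0, 0, 1, 2, 0, 1],
    [2, 0, 1, 1, 0, 1, 1, 2, 0, 0],
    [0, 1, 2, 0, 1, 0, 0, 1, 1, 0],
    [0, 2, 2, 0, 1, 1, 0, 1, 1, 1],
    [1, 1, 1, 0, 0, 0, 1, 0, 1, 0],
    [4, 0, 0, 3, 2, 2, 4, 1, 0, 2],
    [3, 1, 0, 4, 2, 1, 3, 0, 1, 2],
    [4, 0, 1, 4, 1, 2, 4, 1, 0, 1],
])


def amova_oracle(X, groups, pops):
    """Direct mean-square computation from explicit pairwise distances."""
    N = len(X)
    d2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(N)]
                   for i in range(N)])
    def ss_among(labels):
        # SS_total-like sums from pairwise distances within label sets
        tot = 0.0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            tot += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return tot
    ss_total = d2.sum() / (2 * N)
    ss_wg = ss_among(np.asarray(groups))
    ss_wp = ss_among(np.asarray(pops))
    ss_ag, ss_ap = ss_total - ss_wg, ss_wg - ss_wp
    glab, plab = np.unique(groups), np.unique(pops)
    G_, P_ = len(glab), len(plab)
    df = (G_ - 1, P_ - G_, N - P_)
    ms = (ss_ag / df[0], ss_ap / df[1], ss_wp / df[2])
    n_p = {p: np.sum(pops == p) for p in plab}
    N_g = {g: np.sum(groups == g) for g in glab}
    group_of = {p: groups[pops == p][0] for p in plab}
    s1 = sum(sum(n_p[p] ** 2 for p in plab if group_of[p] == g) / N_g[g]
             for g in glab)
    n1 = (N - s1) / df[1]
    n2 = (s1 - sum(v**2 for v in n_p.values()) / N) / df[0]
    n3 = (N - sum(v**2 for v in N_g.values()) / N) / df[0]
    sc = ms[2]
    sb = (ms[1] - sc) / n1
    sa = (ms[0] - sc - n2 * sb) / n3
    return np.array([sa, sb, sc])


class TestAmova:
    def test_identical_individuals(self):
        """All frequency vectors equal: every component is zero and 100%
        of variance sits within populations by convention."""
        meta = AMOVA_META
        # dosage = ploidy: frequency 1 at every locus for every sample
        dos = np.tile(meta["ploidy"].to_numpy()[:, None], (1, 10))
        G = make_matrix(meta, dos)
        res = pg.amova(G, ("region", "population"), n_perm=19, seed=0)
        np.testing.assert_allclose(res.variance_components, 0, atol=1e-12)
        np.testing.assert_allclose(res.percent_variance, [0, 0, 100])

    def test_two_groups_of_clones(self):
        meta = make_meta([(f"a{i}", "pa", "G1", "foothill", 2) for i in range(4)]
                         + [(f"b{i}", "pb", "G2", "alpine", 2) for i in range(4)])
        dos = np.vstack([np.zeros((4, 6), int), np.full((4, 6), 2)])
        G = make_matrix(meta, dos)
        res = pg.amova(G, ("region", "population"), n_perm=19, seed=0)
        assert res.percent_variance[0] > 99.0

    def test_components_match_direct_mean_square_oracle(self):
        G = make_matrix(AMOVA_META, AMOVA_DOSAGES)
        res = pg.amova(G, ("region", "population"), n_perm=19, seed=0)
        X = AMOVA_DOSAGES / AMOVA_META["ploidy"].to_numpy()[:, None]
        expect = amova_oracle(X, AMOVA_META["region"].to_numpy(),
                              AMOVA_META["population"].to_numpy())
        np.testing.assert_allclose(res.variance_components, expect, atol=1e-10)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_population_spanning_groups_rejected(self):
        meta = make_meta([("a", "p1", "G1", "foothill", 2),
                          ("b", "p1", "G2", "foothill", 2)])
        G = make_matrix(meta, [[1], [0]])
        with pytest.raises(ValueError, match="spans"):
            pg.amova(G, ("region", "population"))

    def test_null_permutation_p_uniform(self):
        """Among-group permutation p-values on structureless data follow a
        uniform distribution (KS at alpha = 0.01, 500 runs).

        p = (c+1)/(n_perm+1) lives on a discrete grid; the randomized PIT
        u = p - U/(n_perm+1) is exactly continuous-uniform under the null,
        so the KS test applies cleanly.
        """
        rng = np.random.default_rng(99)
        n_perm = 99
        meta = make_meta(
            [(f"s{i}", f"p{i // 3}", f"G{i // 15}", "foothill", 2)
             for i in range(30)])
        ps = []
        for _ in range(500):
            G = make_matrix(meta, rng.integers(0, 3, size=(30, 12)))
            res = pg.amova(G, ("region", "population"), n_perm=n_perm,
                           seed=int(rng.integers(2**31)))
            ps.append(res.permutation_p["among_groups"])
        u = np.array(ps) - rng.random(len(ps)) / (n_perm + 1)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestGenotypePca:
    def test_duplicated_sample_scores_identical(self):
        rng = np.random.default_rng(6)
        meta = make_meta([(f"s{i}", "p", "NT", "foothill", 2) for i in range(4)])
        dos = rng.integers(0, 3, size=(4, 30))
        dos[1] = dos[0]
        pca = pg.genotype_pca(make_matrix(meta, dos))
        np.testing.assert_allclose(pca.scores[0], pca.scores[1], atol=1e-10)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(8)
        meta = make_meta([(f"s{i}", "p", "NT", "foothill", 2) for i in range(10)])
        pca = pg.genotype_pca(make_matrix(meta, rng.integers(0, 3, (10, 50))))
        assert np.all(np.diff(pca.explained_variance_ratio) <= 1e-12)
        assert pca.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_constant_matrix_rejected(self):
        meta = make_meta([("a", "p", "NT", "foothill", 2),
                          ("b", "p", "NT", "foothill", 2)])
        with pytest.raises(ValueError, match="constant"):
            pg.genotype_pca(make_matrix(meta, [[1, 1], [1, 1]]))

    def test_regional_over_ecotypic_clustering(self, small_study_matrix):
        """PC1-2 separate regions, not ecotypes, under the default
        parallel-origin demography."""
        from sklearn.metrics import silhouette_score

        pca = pg.genotype_pca(small_study_matrix)
        sil_region = silhouette_score(pca.scores[:, :2],
                                      small_study_matrix.samples["region"])
        sil_ecotype = silhouette_score(pca.scores[:, :2],
                                       small_study_matrix.samples["ecotype"])
        assert sil_region > sil_ecotype
        assert sil_region > 0.4


class TestKmeansBic:
    def test_single_cluster_wss_is_total_ss(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        scan = pg.kmeans_bic_scan(X, K_range=[1], n_starts=5, seed=0)
        total_ss = ((X - X.mean(axis=0)) ** 2).sum()
        n = len(X)
        assert scan.bic[0] == pytest.approx(n * np.log(total_ss / n) + np.log(n))
        assert (scan.assignments == 0).all()

    def test_two_separated_clouds(self):
        # enough noise dimensions that splitting a true cluster barely
        # reduces WSS, as in PCA scores of real genotype data
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1.0, size=(25, 30)),
                       rng.normal(10, 1.0, size=(25, 30))])
        scan = pg.kmeans_bic_scan(X, K_range=range(1, 6), n_starts=20, seed=1)
        assert scan.best_K == 2

    def test_k_above_n_skipped(self):
        X = np.random.default_rng(11).normal(size=(4, 2))
        scan = pg.kmeans_bic_scan(X, K_range=range(1, 10), n_starts=5, seed=2)
        assert scan.K_values.max() <= 4


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        W, p = pg.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_exact_case(self):
        """x = {1,2,3} vs y = {4,5,6}: U(x) = 0, exact two-sided p = 0.1
        (2 of the C(6,3) = 20 label splits are as extreme)."""
        W, p = pg.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert W == 0.0
        assert p == pytest.approx(0.1)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(13)
        hits = {0.5: 0, 2.5: 0}
        for shift in hits:
            for _ in range(200):
                x = rng.normal(0, 1, 12)
                y = rng.normal(shift, 1, 12)
                hits[shift] += pg.wilcoxon_rank_sum(x, y)[1] < 0.05
        assert hits[2.5] > hits[0.5]
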