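import math

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from ssrmine.diversity import (
    DistanceMatrix,
    GenotypeMatrix,
    allele_frequencies,
    genetic_distance,
    haversine_distance,
    he_from_freqs,
    individual_heterozygosity,
    locus_stats,
    mantel,
    nj_tree,
    pcoa,
    pic_from_freqs,
)


def matrix_from_rows(rows, loci=None, groups=None):
    """rows: {individual: [genotype per locus]}"""
    individuals = list(rows)
    n_loci = len(next(iter(rows.values())))
    loci = loci or [f"L{k}" for k in range(n_loci)]
    geno = {(ind, loci[k]): rows[ind][k]
            for ind in individuals for k in range(n_loci)}
    return GenotypeMatrix(individuals, loci, geno, groups=groups)


def biallelic_matrix(p, n=50):
    """Genotype table whose allele frequency of allele 1 is exactly p."""
    genes_a = round(2 * n * p)
    n_het = genes_a % 2
    n_hom_a = (genes_a - n_het) // 2
    gts = ([(1, 1)] * n_hom_a + [(1, 2)] * n_het
           + [(2, 2)] * (n - n_hom_a - n_het))
    return matrix_from_rows({f"i{k}": [g] for k, g in enumerate(gts)})


class TestLocusStats:
    def test_printed_biallelic_anchor(self):
        # MAF 0.86 -> He 0.24, PIC 0.21 at 2 decimals
        m = biallelic_matrix(0.86)
        s = locus_stats(m, "L0")
        assert s.maf == pytest.approx(0.86)
        assert round(s.he, 2) == 0.24
        assert round(s.pic, 2) == 0.21

    def test_half_half_closed_form(self):
        s = locus_stats(biallelic_matrix(0.5), "L0")
        assert s.he == pytest.approx(0.5)
        assert s.pic == pytest.approx(0.375)

    def test_monomorphic(self):
        m = matrix_from_rows({"a": [(1, 1)], "b": [(1, 1)]})
        s = locus_stats(m, "L0")
        assert (s.na, s.he, s.ho, s.pic, s.maf) == (1, 0.0, 0.0, 0.0, 1.0)

    def test_ho_counts_heterozygotes(self):
        m = matrix_from_rows({"a": [(1, 2)], "b": [(1, 1)], "c": [(1, 2)],
                              "d": [None]})
        s = locus_stats(m, "L0")
        assert s.ho == pytest.approx(2 / 3)
        assert s.n_genotyped == 3

    def test_subset(self):
        m = matrix_from_rows({"a": [(1, 1)], "b": [(2, 2)], "c": [(3, 3)]})
        s = locus_stats(m, "L0", subset=["a", "b"])
        assert s.na == 2

    def test_all_missing_error(self):
        m = matrix_from_rows({"a": [None], "b": [None]})
        with pytest.raises(ValueError):
            locus_stats(m, "L0")

    def test_pic_le_he_random(self, rng):
        for _ in range(200):
            k = rng.integers(2, 7)
            freqs = rng.dirichlet(np.ones(k))
            assert pic_from_freqs(freqs) <= he_from_freqs(freqs) + 1e-12

    def test_he_two_code_paths_agree(self, rng):
        # independent oracle: gene counting in the test itself
        alleles = [1, 2, 3]
        rows = {f"i{k}": [tuple(sorted(rng.choice(alleles, 2)))]
                for k in range(30)}
        m = matrix_from_rows(rows)
        s = locus_stats(m, "L0")
        counts = {}
        for g in rows.values():
            for a in g[0]:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        he_oracle = 1 - sum((c / total) ** 2 for c in counts.values())
        assert s.he == pytest.approx(he_oracle)
        assert s.he == pytest.approx(
            he_from_freqs(allele_frequencies(m, "L0").values()))


class TestIndividualHeterozygosity:
    def test_ten_of_74(self):
        gts = [(1, 2)] * 10 + [(1, 1)] * 64
        m = matrix_from_rows({"x": gts})
        assert individual_heterozygosity(m, "x") == pytest.approx(13.51, abs=0.005)

    def test_one_of_74(self):
        gts = [(1, 2)] + [(1, 1)] * 73
        m = matrix_from_rows({"x": gts})
        assert individual_heterozygosity(m, "x") == pytest.approx(1.35, abs=0.005)

    def test_fully_homozygous(self):
        m = matrix_from_rows({"x": [(1, 1)] * 5})
        assert individual_heterozygosity(m, "x") == 0.0


class TestGeneticDistance:
    def test_identical_homozygotes_zero(self):
        m = matrix_from_rows({"a": [(1, 1), (2, 2)], "b": [(1, 1), (2, 2)]})
        for measure in ("nei1972", "shared_allele"):
            d = genetic_distance(m, measure)
            assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_alleles_shared_one(self):
        m = matrix_from_rows({"a": [(1, 1), (3, 3)], "b": [(2, 2), (4, 4)]})
        d = genetic_distance(m, "shared_allele")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_aa_vs_ab_half(self):
        m = matrix_from_rows({"a": [(1, 1)], "b": [(1, 2)]})
        d = genetic_distance(m, "shared_allele")
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion(self):
        m = matrix_from_rows({"a": [(1, 1), None], "b": [(1, 1), (5, 5)]})
        d = genetic_distance(m, "shared_allele")
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_no_cogenotyped_locus_is_nan(self):
        m = matrix_from_rows({"a": [(1, 1), None], "b": [None, (5, 5)]})
        d = genetic_distance(m, "shared_allele")
        assert math.isnan(d.values[0, 1])

    def test_symmetry_zero_diagonal(self, rng):
        rows = {f"i{k}": [tuple(sorted(rng.choice([1, 2, 3], 2)))
                          for _ in range(5)] for k in range(6)}
        for measure in ("nei1972", "shared_allele"):
            d = genetic_distance(matrix_from_rows(rows), measure)
            assert np.allclose(d.values, d.values.T)
            assert np.allclose(np.diag(d.values), 0)


# ---------------------------------------------------------------------------
# trees

def tree_distances(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]])
    return out


def random_additive_tree(rng, n):
    """Random topology + branch lengths; returns the leaf distance matrix."""
    nodes = [(i,) for i in range(n)]
    dist = np.zeros((n, n))
    # build by random joins, tracking leaf-to-root-ish path increments
    depth = {i: 0.0 for i in range(n)}
    clusters = [[i] for i in range(n)]
    add = np.zeros((n, n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0, 2)
        for a in clusters[i]:
            for b in clusters[j]:
                add[a, b] = add[b, a] = depth[a] + bi + depth[b] + bj
        for a in clusters[i]:
            depth[a] += bi
        for b in clusters[j]:
            depth[b] += bj
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return add


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # [DERIVED] distances from tree ((A:1,B:2):1,(C:3,D:1))
        labels = ["A", "B", "C", "D"]
        d = DistanceMatrix(labels, np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float))
        newick = nj_tree(d)
        assert np.allclose(tree_distances(newick, labels), d.values, atol=1e-9)

    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
        assert nj_tree(d) == "(A:1,B:2,C:3);"

    def test_random_additive_trees_recovered(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            add = random_additive_tree(rng, n)
            labels = [f"t{i}" for i in range(n)]
            newick = nj_tree(DistanceMatrix(labels, add))
            assert np.allclose(tree_distances(newick, labels), add, atol=1e-8)

    def test_ultrametric_distances_preserved(self):
        labels = ["A", "B", "C", "D"]
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        newick = nj_tree(DistanceMatrix(labels, d))
        assert np.allclose(tree_distances(newick, labels), d, atol=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))


class TestPCoA:
    def test_collinear_points_one_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix([f"i{k}" for k in range(4)], d))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_2d_reconstruction(self, rng):
        pts = rng.normal(size=(15, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"i{k}" for k in range(15)], d))
        coords = res.coordinates
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d2, d, atol=1e-9)

    def test_eigenvalue_conservation(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"i{k}" for k in range(10)], d))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert pos.sum() == pytest.approx((res.coordinates ** 2).sum())

    def test_sign_convention(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"i{k}" for k in range(8)], d))
        for j in range(res.coordinates.shape[1]):
            col = res.coordinates[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_axes_ordered_descending(self, rng):
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"i{k}" for k in range(10)], d))
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)


def _random_distance(rng, n):
    pts = rng.normal(size=(n, 3))
    return np.linalg.norm(pts[:, None] - pts[None, :], axis=2)


class TestMantel:
    def test_self_correlation(self, rng):
        d = _random_distance(rng, 12)
        ids = [f"i{k}" for k in range(12)]
        res = mantel(DistanceMatrix(ids, d), DistanceMatrix(ids, d),
                     n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_perfect_negative_linear(self, rng):
        d = _random_distance(rng, 10)
        neg = -0.5 * d + d.max()
        np.fill_diagonal(neg, 0)
        ids = [f"i{k}" for k in range(10)]
        res = mantel(DistanceMatrix(ids, d), DistanceMatrix(ids, neg),
                     n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_constant_matrix_error(self, rng):
        d = _random_distance(rng, 8)
        c = np.ones((8, 8))
        np.fill_diagonal(c, 0)
        ids = [f"i{k}" for k in range(8)]
        with pytest.raises(ValueError):
            mantel(DistanceMatrix(ids, c), DistanceMatrix(ids, d), seed=0)

    def test_seed_reproducible(self, rng):
        ids = [f"i{k}" for k in range(10)]
        d1 = DistanceMatrix(ids, _random_distance(rng, 10))
        d2 = DistanceMatrix(ids, _random_distance(rng, 10))
        assert mantel(d1, d2, 99, seed=5) == mantel(d1, d2, 99, seed=5)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(42)
        ids = [f"i{k}" for k in range(15)]
        ps = []
        for rep in range(100):
            d1 = DistanceMatrix(ids, _random_distance(rng, 15))
            d2 = DistanceMatrix(ids, _random_distance(rng, 15))
            ps.append(mantel(d1, d2, 99, seed=rep).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestHaversine:
    def test_known_quarter_meridian(self):
        coords = {"a": (0.0, 0.0), "b": (90.0, 0.0)}
        d = haversine_distance(coords, ["a", "b"])
        assert d.values[0, 1] == pytest.approx(10007.5, rel=1e-3)

    def test_zero_for_same_point(self):
        coords = {"a": (13.7, 100.5), "b": (13.7, 100.5)}
        d = haversine_distance(coords, ["a", "b"])
        assert d.values[0, 1] == pytest.approx(0.0)


class TestIO:
    def test_genotype_tsv_round_trip(self, tmp_path, rng):
        rows = {f"i{k}": [tuple(sorted(rng.choice([90, 92, 94], 2))), None]
                for k in range(5)}
        m = matrix_from_rows(rows, groups={"i0": "tall", "i1": "dwarf"})
        path = tmp_path / "geno.tsv"
        m.to_tsv(path)
        again = GenotypeMatrix.from_tsv(path)
        assert again.individuals == m.individuals
        assert again.loci == m.loci
        for ind in m.individuals:
            for locus in m.loci:
                assert again.genotype(ind, locus) == m.genotype(ind, locus)
        assert again.groups == m.groups

    def test_structure_export(self, tmp_path):
        m = matrix_from_rows({"a": [(1, 2)], "b": [None]},
                             groups={"a": "g1", "b": "g2"})
        path = tmp_path / "structure.txt"
        m.to_structure(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 5  # header + 2 rows per individual
        assert lines[1].split("\t") == ["a", "1", "1"]
        assert lines[2].split("\t") == ["a", "1", "2"]
        assert lines[3].split("\t") == ["b", "2", "-9"]

    def test_distance_csv_round_trip(self, tmp_path, rng):
        ids = ["a", "b", "c"]
        d = DistanceMatrix(ids, _random_distance(rng, 3))
        path = tmp_path / "dist.csv"
        d.to_csv(path)
        again = DistanceMatrix.from_csv(path)
        assert again.ids == ids
        assert np.allclose(again.values, d.values, atol=1e-6)
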