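import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from strpopgen.popstruct import (
    DistanceMatrix,
    mds,
    nei_distance,
    nei_distance_matrix,
    read_phylip_distances,
    upgma,
    write_phylip_distances,
)
from strpopgen.strdata import allele_frequencies


def random_ultrametric(rng, n):
    """Random ultrametric matrix built from a random agglomeration order."""
    d = np.zeros((n, n))
    clusters = [[i] for i in range(n)]
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * height
        clusters[i] = clusters[i] + clusters.pop(j)
    return DistanceMatrix([f"t{i}" for i in range(n)], d)


class TestNeiDistance:
    def test_identical_populations_distance_zero(self):
        f = {"L": {100: 0.3, 110: 0.7}}
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_one_locus(self):
        fx = {"L": {100: 1.0}}
        fy = {"L": {100: 0.5, 110: 0.5}}
        assert nei_distance(fx, fy) == pytest.approx(0.34657, abs=5e-6)

    def test_disjoint_alleles_infinite(self):
        fx = {"L": {100: 1.0}}
        fy = {"L": {110: 1.0}}
        assert nei_distance(fx, fy) == np.inf

    def test_symmetric_and_relabel_invariant(self, rng):
        fx = {"L": {100: 0.2, 110: 0.5, 120: 0.3}}
        fy = {"L": {100: 0.6, 110: 0.1, 120: 0.3}}
        assert nei_distance(fx, fy) == pytest.approx(nei_distance(fy, fx))
        relab = lambda f: {"L": {a + 500: p for a, p in f["L"].items()}}
        assert nei_distance(relab(fx), relab(fy)) == pytest.approx(nei_distance(fx, fy))

    def test_matrix_from_genotypes(self, two_pop_table):
        dm = nei_distance_matrix(allele_frequencies(two_pop_table))
        assert dm.ids == ["alpha", "beta"]
        assert dm.values[0, 1] > 0


class TestUpgma:
    def test_two_taxa(self):
        t = upgma(DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]])))
        assert t.newick() == "(A:2,B:2);"

    def test_three_taxa_hand_agglomeration(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        t = upgma(DistanceMatrix(["A", "B", "C"], d))
        assert t.newick() == "((A:1,B:1):1,C:2);"
        assert t.height == 2.0

    def test_ultrametric_input_reproduced_by_cophenetic(self, rng):
        for n in (4, 7, 10):
            dm = random_ultrametric(rng, n)
            t = upgma(dm)
            coph = t.cophenetic()
            order = [coph.ids.index(i) for i in dm.ids]
            got = coph.values[np.ix_(order, order)]
            assert np.allclose(got, dm.values, atol=1e-9)

    def test_agrees_with_scipy_average_linkage(self, rng):
        """Independent oracle: cophenetic distances from scipy UPGMA."""
        for _ in range(3):
            pts = rng.normal(size=(8, 3))
            d = squareform(pdist(pts))
            dm = DistanceMatrix([f"t{i}" for i in range(8)], d)
            t = upgma(dm)
            coph = t.cophenetic()
            order = [coph.ids.index(i) for i in dm.ids]
            got = coph.values[np.ix_(order, order)]
            z = hierarchy.linkage(squareform(d), method="average")
            want = squareform(hierarchy.cophenet(z))
            assert np.allclose(got, want, atol=1e-9)

    def test_leaf_order_invariance_under_permutation(self, rng):
        dm = random_ultrametric(rng, 6)
        t1 = upgma(dm)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix(
            [dm.ids[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t2 = upgma(dm2)
        c1, c2 = t1.cophenetic(), t2.cophenetic()
        order = [c2.ids.index(i) for i in c1.ids]
        assert np.allclose(c1.values, c2.values[np.ix_(order, order)], atol=1e-9)

    def test_infinite_distance_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A", "B"], d))

    def test_same_subpopulation_joins_before_diverged(self):
        """Samples drawn from the same latent frequencies merge first."""
        from strpopgen.synthdata import LocusSpec, SimulationConfig, simulate_genotypes
        from strpopgen.strdata import allele_frequencies as af

        loci = [
            LocusSpec("A", labels=(100, 110, 120, 130), ancestral=(0.4, 0.3, 0.2, 0.1)),
            LocusSpec("B", labels=(80, 90, 100), ancestral=(0.5, 0.3, 0.2)),
            LocusSpec("C", labels=(60, 70, 80, 90), ancestral=(0.25, 0.25, 0.25, 0.25)),
        ]
        hits = 0
        for seed in range(20):
            # pop1/pop2 share one divergence draw (same spawn key via same
            # config); pop3 is made divergent by raising theta in a second run
            base = SimulationConfig(
                n_populations=2, n_per_population=100, loci=loci, theta=0.002, seed=seed
            )
            far = SimulationConfig(
                n_populations=3, n_per_population=100, loci=loci, theta=0.15, seed=seed
            )
            gt_near, _ = simulate_genotypes(base)
            gt_far, _ = simulate_genotypes(far)
            merged_calls = {
                k: np.vstack([gt_near.calls[k], gt_far.calls[k][gt_far.populations == "pop3"]])
                for k in gt_near.calls
            }
            n3 = int((gt_far.populations == "pop3").sum())
            from strpopgen.strdata import GenotypeTable

            gt = GenotypeTable(
                gt_near.panel,
                gt_near.sample_ids + [f"far_{i}" for i in range(n3)],
                list(gt_near.populations) + ["far"] * n3,
                merged_calls,
            )
            tree = upgma(nei_distance_matrix(af(gt)))
            first_merge = min(_internal_nodes(tree), key=lambda c: c.height)
            if sorted(first_merge.leaves()) == ["pop1", "pop2"]:
                hits += 1
        assert hits >= 19


def _internal_nodes(node):
    out = [] if node.is_leaf else [node]
    for c in node.children:
        out += _internal_nodes(c)
    return out


class TestMds:
    def test_planted_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        o = mds(DistanceMatrix([f"p{i}" for i in range(6)], d), dims=2)
        assert o.stress < 1e-6
        got = squareform(pdist(o.coords))
        assert np.allclose(got, d, atol=1e-6)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        o = mds(DistanceMatrix(["a", "b", "c"], d), dims=2)
        got = squareform(pdist(o.coords))
        assert np.allclose(got, d, atol=1e-9)

    def test_duplicate_population_coincident_points(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        o = mds(DistanceMatrix(["a", "a2", "b"], d), dims=2)
        assert np.allclose(o.coords[0], o.coords[1], atol=1e-9)

    def test_coordinates_centered(self, rng):
        pts = rng.normal(size=(5, 2)) + 10.0
        d = squareform(pdist(pts))
        o = mds(DistanceMatrix([f"p{i}" for i in range(5)], d), dims=2)
        assert np.allclose(o.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self, rng):
        """Independent oracle: principal coordinates from scikit-bio."""
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        o = mds(DistanceMatrix([f"p{i}" for i in range(7)], d), dims=2)
        res = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        want = res.samples.values[:, :2]
        for k in range(2):  # eigenvectors defined up to sign
            assert np.allclose(np.abs(o.coords[:, k]), np.abs(want[:, k]), atol=1e-6)

    def test_stress_majorization_not_worse_than_classical(self, rng):
        pts = rng.normal(size=(8, 4))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"p{i}" for i in range(8)], d)
        classical = mds(dm, dims=2)
        refined = mds(dm, dims=2, algorithm="stress-majorization", seed=0)
        assert refined.stress <= classical.stress + 1e-9

    def test_dims_bound(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            mds(DistanceMatrix(["a", "b", "c"], d), dims=3)


class TestPhylipIO:
    def test_roundtrip(self, tmp_path, rng):
        pts = rng.normal(size=(5, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"pop{i}" for i in range(5)], d)
        p = tmp_path / "d.phy"
        write_phylip_distances(dm, p)
        back = read_phylip_distances(p)
        assert back.ids == dm.ids
        assert np.allclose(back.values, dm.values, atol=1e-9)
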