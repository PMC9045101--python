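import itertools

import numpy as np
import pytest

from mica.io_formats import DistanceMatrix, OTUTable
from mica.diversity_stats import (
    alpha_diversity,
    bray_curtis_matrix,
    compare_groups,
    mantel,
    pcoa,
    permanova,
    rda_variance,
    shared_otu_counts,
    upgma_dendrogram,
)


def _dm_from_points(points):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(len(pts))], (d + d.T) / 2)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, richness, shannon, pielou",
        [
            ([10, 10, 10, 10], 4, np.log(4), 1.0),
            ([42], 1, 0.0, 0.0),
            # -sum(p ln p) for p = (1/6, 2/6, 3/6)
            ([1, 2, 3], 3, 1.0114042647073518, 1.0114042647073518 / np.log(3)),
        ],
    )
    def test_known_values(self, counts, richness, shannon, pielou):
        t = OTUTable(["s"] , [f"o{i}" for i in range(len(counts))], np.array([counts]))
        rec = alpha_diversity(t)[0]
        assert rec.richness == richness
        assert rec.shannon == pytest.approx(shannon, abs=1e-12)
        assert rec.pielou == pytest.approx(pielou, abs=1e-12)

    def test_shannon_maximal_iff_uniform(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 50, size=8)
            t = OTUTable(["s"], [f"o{i}" for i in range(8)], counts[None, :])
            rec = alpha_diversity(t)[0]
            assert rec.shannon <= np.log(8) + 1e-12
            assert 0.0 <= rec.pielou <= 1.0


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        stat, p = compare_groups([1, 2, 3, 1, 2, 3], list("aaabbb"), test="mann_whitney")
        assert p == pytest.approx(1.0)

    def test_extreme_separation_reaches_minimal_exact_p(self):
        # n=m=3, complete separation: two-sided exact p = 2 * 1/C(6,3) = 0.1
        stat, p = compare_groups(
            [1, 2, 3, 101, 102, 103], list("aaabbb"), test="mann_whitney"
        )
        assert p == pytest.approx(0.1)

    def test_mann_whitney_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "b", "c"], test="mann_whitney")

    def test_kruskal_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(size=15)
            groups = np.repeat(["a", "b", "c"], 5)
            _, p = compare_groups(vals, groups, test="kruskal_wallis")
            hits += p <= 0.05
        # binomial CI around 0.05 at 400 reps
        assert hits / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OTUTable(
            ["a", "b", "c"],
            ["x", "y", "z", "w"],
            np.array([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]]),
        )
        bc = bray_curtis_matrix(t)
        assert bc.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert bc.values[0, 2] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = OTUTable(["a", "b"], ["x", "y", "z"], np.array([[1, 1, 0], [0, 1, 1]]))
        bc = bray_curtis_matrix(t, use_relative=False)
        assert bc.values[0, 1] == pytest.approx(0.5)

    def test_values_in_unit_interval(self, rng):
        counts = rng.integers(0, 20, size=(6, 10))
        counts[:, 0] += 1
        t = OTUTable([f"s{i}" for i in range(6)], [f"o{i}" for i in range(10)], counts)
        bc = bray_curtis_matrix(t)
        assert (bc.values >= 0).all() and (bc.values <= 1 + 1e-12).all()


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        res = pcoa(_dm_from_points(x))
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        coords = res.coordinates[:, 0]
        gaps = np.abs(np.diff(np.sort(coords)))
        assert np.allclose(sorted(gaps), [1.0, 2.0], atol=1e-9)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_planar_points_need_two_axes(self, rng):
        pts = rng.normal(size=(10, 2))
        res = pcoa(_dm_from_points(pts))
        assert res.proportion_explained[:2].sum() == pytest.approx(1.0, abs=1e-9)
        # Euclidean input: no meaningful negative eigenvalues
        assert res.eigenvalues.min() > -1e-9 * res.eigenvalues.max()


class TestPermanova:
    def test_two_tight_clusters_saturate_significance(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (6, 2)), rng.normal(10, 0.01, (6, 2))])
        res = permanova(_dm_from_points(pts), ["a"] * 6 + ["b"] * 6, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r_squared > 0.9

    def test_null_p_values_calibrated(self, rng):
        hits = 0
        reps = 300
        for rep in range(reps):
            pts = rng.normal(size=(12, 3))
            res = permanova(
                _dm_from_points(pts), ["a"] * 6 + ["b"] * 6, n_permutations=199, seed=rep
            )
            assert res.p_value >= 1 / 200
            hits += res.p_value <= 0.05
        assert hits / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_group_rejected(self):
        dm = _dm_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            permanova(dm, ["a", "a", "a"], n_permutations=99, seed=0)

    def test_seed_reproducible(self, rng):
        pts = rng.normal(size=(10, 2))
        dm = _dm_from_points(pts)
        groups = ["a"] * 5 + ["b"] * 5
        r1 = permanova(dm, groups, n_permutations=199, seed=7)
        r2 = permanova(dm, groups, n_permutations=199, seed=7)
        assert r1 == r2


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = _dm_from_points(rng.normal(size=(8, 2)))
        r, _ = mantel(dm, dm, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_transform_preserves_pearson(self, rng):
        dm = _dm_from_points(rng.normal(size=(8, 2)))
        dm2 = DistanceMatrix(dm.ids, 3.0 * dm.values)
        r, _ = mantel(dm, dm2, method="pearson", n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_id_mismatch_rejected(self, rng):
        d1 = _dm_from_points(rng.normal(size=(5, 2)))
        d2 = DistanceMatrix(["x0", "x1", "x2", "x3", "x4"], d1.values)
        with pytest.raises(Exception):
            mantel(d1, d2, n_permutations=99, seed=0)


class TestUPGMA:
    def test_hand_agglomeration(self):
        # d(A,B)=1, d(A,C)=d(B,C)=4: topology ((A,B),C), A and B at height 0.5
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        )
        tree = upgma_dendrogram(dm)
        tip = {t.name: t for t in tree.tips()}
        assert tip["A"].length == pytest.approx(0.5)
        assert tip["B"].length == pytest.approx(0.5)
        assert tip["A"].distance(tip["B"]) == pytest.approx(1.0)
        assert tip["A"].distance(tip["C"]) == pytest.approx(4.0)

    def test_two_ids_single_cherry(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma_dendrogram(dm)
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(1.5)

    def test_ultrametric_output(self, rng):
        pts = rng.normal(size=(7, 3))
        tree = upgma_dendrogram(_dm_from_points(pts))
        depths = [tree.distance(t) for t in tree.tips()]
        assert np.ptp(depths) < 1e-9


class TestRDA:
    def test_community_exactly_linear_in_predictor(self, rng):
        x = rng.normal(size=20)
        base = np.array([5.0, 3.0, 2.0, 1.0])
        loadings = np.array([0.5, -0.2, -0.2, -0.1])
        comp = base[None, :] + np.outer(x, loadings)
        counts = np.rint(comp * 1000).astype(int)
        t = OTUTable([f"s{i}" for i in range(20)], list("abcd"), counts)
        explained, axes = rda_variance(t, x, hellinger=False)
        assert explained > 0.99
        assert axes[0] == pytest.approx(explained, abs=1e-6)

    def test_random_predictors_explain_little(self, rng):
        counts = rng.integers(1, 100, size=(40, 15))
        t = OTUTable([f"s{i}" for i in range(40)], [f"o{i}" for i in range(15)], counts)
        x = rng.normal(size=(40, 2))
        explained, _ = rda_variance(t, x)
        # null expectation ~ p/(n-1)
        assert explained < 5 * 2 / 39

    def test_too_few_samples_rejected(self, rng):
        counts = rng.integers(1, 10, size=(3, 4))
        t = OTUTable(["a", "b", "c"], list("wxyz"), counts)
        with pytest.raises(ValueError):
            rda_variance(t, rng.normal(size=(3, 2)))


class TestSharedOTUCounts:
    def test_two_group_example(self):
        regions = shared_otu_counts({"A": {"1", "2"}, "B": {"2", "3"}})
        assert regions[frozenset(["A", "B"])] == 1
        assert regions[frozenset(["A"])] == 1
        assert regions[frozenset(["B"])] == 1

    def test_identical_sets_all_in_core(self):
        s = {f"o{i}" for i in range(7)}
        regions = shared_otu_counts({g: set(s) for g in "ABCD"})
        assert regions[frozenset("ABCD")] == 7
        assert sum(v for k, v in regions.items() if k != frozenset("ABCD")) == 0

    def test_matches_brute_force_enumeration(self, rng):
        otus = [f"o{i}" for i in range(60)]
        groups = {g: {o for o in otus if rng.random() < 0.4} for g in "ABCD"}
        regions = shared_otu_counts(groups)
        names = list(groups)
        for r in range(1, 5):
            for members in itertools.combinations(names, r):
                expected = sum(
                    1
                    for o in otus
                    if all(o in groups[m] for m in members)
                    and not any(o in groups[m] for m in names if m not in members)
                )
                assert regions[frozenset(members)] == expected

    def test_counts_from_tables(self, small_table):
        regions = shared_otu_counts({"g1": small_table, "g2": {"o1", "zzz"}})
        assert regions[frozenset(["g1", "g2"])] == 1  # o1
        assert regions[frozenset(["g1"])] == 3  # o2, o3, o4
        assert regions[frozenset(["g2"])] == 1  # zzz
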