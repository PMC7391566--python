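import itertools
import math

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
from scipy.spatial.distance import pdist, squareform

import traitspaces as ts
from conftest import random_space

SQRT_HALF = math.sqrt(0.5)


class TestToyValues:
    """Hand-derived values on tiny configurations."""

    def test_centroid(self, unit_square):
        np.testing.assert_allclose(ts.centroid(unit_square), [0.5, 0.5])
        np.testing.assert_allclose(ts.centroid(np.array([[3.0, -2.0]])), [3, -2])
        np.testing.assert_allclose(ts.centroid(np.array([[-1.0, -1], [1, 1]])), [0, 0])

    @pytest.mark.parametrize("measure, expected", [
        ("mean_distance_from_centroid", SQRT_HALF),
        ("sum_of_variances", 2 / 3),
        ("sum_of_ranges", 2.0),
        ("ellipsoid_volume", math.pi / 3),
        ("mst_average_distance", 1.0),
        ("mst_evenness", 1.0),
        ("mean_nearest_neighbour_distance", 1.0),
        ("average_displacement", (2 + math.sqrt(2)) / (4 * SQRT_HALF)),
    ])
    def test_unit_square(self, unit_square, measure, expected):
        mv = ts.measure_registry.get(measure)(unit_square)
        assert mv.valid
        assert mv.value == pytest.approx(expected, abs=1e-9)

    def test_one_dimensional_cases(self):
        two = np.array([[0.0], [2.0]])
        assert ts.mean_distance_from_centroid(two).value == pytest.approx(1.0)
        assert ts.mean_nearest_neighbour_distance(two).value == pytest.approx(2.0)
        assert ts.mst_average_distance(np.array([[0.0], [5.0]])).value == pytest.approx(5.0)
        # MST of {0,1,2}: edges (0-1),(1-2), total 2
        tree = ts.minimum_spanning_tree(squareform(pdist(np.array([[0.0], [1], [2]]))))
        assert tree.total_length == pytest.approx(2.0)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]
        assert ts.mst_evenness(np.array([[0.0], [1], [2]])).value == pytest.approx(1.0)

    def test_mst_evenness_uneven_edges(self):
        # MST of {0,1,10} has edges 1 and 9: FEve = (0.1 + 0.5 - 0.5)/0.5 = 0.2
        assert ts.mst_evenness(np.array([[0.0], [1], [10]])).value == pytest.approx(0.2)
        # edges 1 and 10: FEve = (1/11)/(1/2) = 2/11
        assert ts.mst_evenness(np.array([[0.0], [1], [11]])).value == pytest.approx(2 / 11)

    def test_nearest_neighbour_with_coincident_points(self):
        x = np.array([[0.0, 0], [0, 0], [9, 0]])
        assert ts.mean_nearest_neighbour_distance(x).value == pytest.approx(3.0)

    def test_sum_of_variances_degenerate(self):
        assert ts.sum_of_variances(np.zeros((5, 3))).value == 0.0
        assert not ts.sum_of_variances(np.ones((1, 3))).valid

    def test_single_point_values(self):
        p = np.array([[2.0, 3.0]])
        assert ts.mean_distance_from_centroid(p).value == 0.0
        assert ts.sum_of_ranges(p).value == 0.0

    def test_average_displacement_centred_space_is_one(self):
        x = np.random.default_rng(0).normal(size=(40, 3))
        centred = x - x.mean(axis=0)
        assert ts.average_displacement(centred).value == pytest.approx(1.0, abs=1e-12)

    def test_average_displacement_coincident_points_invalid(self):
        mv = ts.average_displacement(np.ones((4, 2)))
        assert not mv.valid and "coincide" in mv.reason

    def test_ellipsoid_volume_identity_covariance_2d(self):
        # data engineered to have exactly identity sample covariance
        x = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]) * math.sqrt(3 / 2)
        assert ts.ellipsoid_volume(x).value == pytest.approx(math.pi)

    def test_ellipsoid_volume_rank_deficient_is_invalid(self):
        x = np.random.default_rng(1).normal(size=(10, 20))
        mv = ts.ellipsoid_volume(x)
        assert not mv.valid and "multidimensionality" in mv.reason


def _prufer_trees(n: int) -> list[np.ndarray]:
    """All labelled spanning trees on n nodes via Prüfer sequences."""
    if n == 2:
        return [np.array([[0, 1]])]
    trees = []
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = np.ones(n, dtype=int)
        for v in seq:
            degree[v] += 1
        edges = []
        avail = list(seq)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        for v in avail:
            leaf = leaves.pop(0)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect
                bisect.insort(leaves, v)
        edges.append((leaves[0], leaves[1]))
        trees.append(np.array(edges))
    return trees


class TestMinimumSpanningTree:
    def test_unit_square_total_length(self, unit_square):
        tree = ts.minimum_spanning_tree(ts.distance_matrix(unit_square))
        assert tree.total_length == pytest.approx(3.0)
        assert len(tree.edges) == 3

    def test_two_points(self):
        tree = ts.minimum_spanning_tree(np.array([[0.0, 5], [5, 0]]))
        assert tree.edges == ((0, 1, 5.0),)

    def test_structure_invariants(self):
        sp = random_space(25, 3, seed=4)
        tree = ts.minimum_spanning_tree(ts.distance_matrix(sp))
        assert len(tree.edges) == 24
        # connected and acyclic: union-find over the returned edges
        parent = list(range(25))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        for i, j, _ in tree.edges:
            ri, rj = find(i), find(j)
            assert ri != rj  # acyclic
            parent[ri] = rj
        assert len({find(i) for i in range(25)}) == 1  # connected

    def test_brute_force_oracle_small_instances(self):
        """MST total length equals the exhaustive minimum over all spanning trees."""
        rng = np.random.default_rng(12345)
        tree_cache = {}
        for _ in range(100):
            n = int(rng.integers(3, 8))
            x = rng.normal(size=(n, int(rng.integers(1, 4))))
            dm = squareform(pdist(x))
            if n not in tree_cache:
                tree_cache[n] = _prufer_trees(n)
            brute = min(dm[t[:, 0], t[:, 1]].sum() for t in tree_cache[n])
            ours = ts.minimum_spanning_tree(dm).total_length
            assert ours == pytest.approx(brute, rel=1e-12)

    def test_matches_scipy_total_length(self):
        for seed in range(10):
            sp = random_space(40, 4, seed=seed)
            dm = ts.distance_matrix(sp)
            ours = ts.minimum_spanning_tree(dm).total_length
            ref = scipy_mst(dm).sum()
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ts.minimum_spanning_tree(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            ts.minimum_spanning_tree(np.zeros((2, 3)))


SIZE_DENSITY_MEASURES = [
    "mean_distance_from_centroid", "sum_of_variances", "sum_of_ranges",
    "ellipsoid_volume", "mst_average_distance", "mst_evenness",
    "mean_nearest_neighbour_distance",
]

# exponent of s in f(s*x) = s^k f(x); None marks scale-invariant measures
HOMOGENEITY_DEGREE = {
    "mean_distance_from_centroid": 1,
    "sum_of_variances": 2,
    "sum_of_ranges": 1,
    "mst_average_distance": 1,
    "mean_nearest_neighbour_distance": 1,
    "mst_evenness": 0,
    "average_displacement": 0,
}


class TestMeasureProperties:
    @pytest.mark.parametrize("measure", SIZE_DENSITY_MEASURES)
    def test_translation_invariance(self, measure):
        fn = ts.measure_registry.get(measure)
        for seed in range(5):
            sp = random_space(20, 3, seed=seed)
            shifted = ts.TraitSpace(sp.data + np.array([10.0, -3.0, 7.0]))
            a, b = fn(sp).value, fn(shifted).value
            assert b == pytest.approx(a, rel=1e-10)

    def test_average_displacement_not_translation_invariant(self):
        sp = random_space(20, 3, seed=0)
        shifted = ts.TraitSpace(sp.data + np.array([10.0, -3.0, 7.0]))
        a = ts.average_displacement(sp).value
        b = ts.average_displacement(shifted).value
        assert abs(a - b) > 0.1

    @pytest.mark.parametrize("measure, degree", sorted(HOMOGENEITY_DEGREE.items()))
    def test_homogeneity_under_scaling(self, measure, degree):
        fn = ts.measure_registry.get(measure)
        s = 2.5
        for seed in range(3):
            sp = random_space(15, 4, seed=seed)
            a = fn(sp).value
            b = fn(ts.TraitSpace(s * sp.data)).value
            assert b == pytest.approx(s ** degree * a, rel=1e-9)

    def test_ellipsoid_volume_scales_with_s_to_the_d(self):
        sp = random_space(30, 3, seed=2)
        a = ts.ellipsoid_volume(sp).value
        b = ts.ellipsoid_volume(ts.TraitSpace(2.0 * sp.data)).value
        assert b == pytest.approx(2.0 ** 3 * a, rel=1e-9)

    @pytest.mark.parametrize("measure", sorted(HOMOGENEITY_DEGREE) + ["ellipsoid_volume"])
    def test_permutation_invariance(self, measure):
        fn = ts.measure_registry.get(measure)
        rng = np.random.default_rng(3)
        sp = random_space(18, 4, seed=3)
        permuted = ts.TraitSpace(
            sp.data[rng.permutation(18)][:, rng.permutation(4)])
        assert fn(permuted).value == pytest.approx(fn(sp).value, rel=1e-10)

    def test_mst_evenness_bounded_in_unit_interval(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n, d = int(rng.integers(3, 30)), int(rng.integers(1, 6))
            v = ts.mst_evenness(rng.normal(size=(n, d))).value
            assert 0.0 <= v <= 1.0

    def test_ellipsoid_volume_log_space_matches_direct_formula(self):
        from scipy.special import gamma
        for seed in range(10):
            sp = random_space(50, 3, seed=seed)
            lam = np.linalg.eigvalsh(np.cov(sp.data, rowvar=False))
            direct = math.pi ** 1.5 / gamma(2.5) * np.prod(np.sqrt(lam))
            assert ts.ellipsoid_volume(sp).value == pytest.approx(direct, rel=1e-8)

    def test_sum_of_ranges_monotone_under_subsetting(self):
        sp = random_space(30, 4, seed=6)
        full = ts.sum_of_ranges(sp).value
        sub = ts.sum_of_ranges(sp.data[:15]).value
        assert sub <= full


class TestRegistry:
    def test_builtins_present(self):
        names = ts.measure_registry.list()
        assert len(names) == 8
        assert ts.measure_registry.category("sum_of_variances") == "size"
        assert ts.measure_registry.category("mst_evenness") == "density"
        assert ts.measure_registry.category("average_displacement") == "position"

    def test_get_applies(self, unit_square):
        fn = ts.measure_registry.get("sum_of_variances")
        assert fn(unit_square).value == pytest.approx(2 / 3)

    def test_register_user_measure(self, unit_square):
        def const(space, **_):
            return ts.MeasureValue("const42", "size", 42.0)

        ts.measure_registry.register("const42", "size", const)
        try:
            assert ts.measure_registry.get("const42")(unit_square).value == 42.0
            with pytest.raises(ValueError, match="already registered"):
                ts.measure_registry.register("const42", "size", const)
        finally:
            ts.measure_registry._measures.pop("const42")

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="unknown measure"):
            ts.measure_registry.get("hypervolume")


class TestApplyMeasures:
    def test_matches_individual_calls(self):
        sp = random_space(30, 5, seed=8)
        batch = {mv.name: mv.value for mv in ts.apply_measures(sp)}
        for name in ts.BUILTIN_MEASURES:
            single = ts.measure_registry.get(name)(sp)
            assert batch[name] == pytest.approx(single.value, rel=1e-12)
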