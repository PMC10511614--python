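"""Coverage classification, distribution indices and group statistics."""

import itertools
import math

import numpy as np
import pytest

from aaastrain import (
    classify_elements,
    coverage_fraction,
    distribution_indices,
    ks_normality,
    mannwhitney_left,
)
from aaastrain.core import QuadMesh
from aaastrain.regions import ElementLabels, significance_stars
from aaastrain.strain import AmplitudeField

from conftest import cylinder_grid


def _flat_element(width=2.0, height=1.0):
    """Planar rectangular element in the z = 0 plane."""
    return np.array(
        [[0, 0, 0], [width, 0, 0], [width, height, 0], [0, height, 0]], dtype=float
    )


class TestCoverage:
    def test_no_calcification_gives_zero(self):
        assert coverage_fraction(_flat_element(), np.empty((0, 3)), 0.5) == 0.0
        assert coverage_fraction(_flat_element(), None, 0.5) == 0.0

    def test_dense_cover_gives_one(self):
        elem = _flat_element()
        gx, gy = np.meshgrid(np.linspace(0, 2, 40), np.linspace(0, 1, 20))
        cloud = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=-1)
        assert coverage_fraction(elem, cloud, 0.2) == 1.0

    def test_half_plane_patch_covers_half(self):
        # patch over the s > 0 half (y > 0.5): lattice counting gives 0.5
        elem = _flat_element()
        gx, gy = np.meshgrid(np.linspace(0, 2, 80), np.linspace(0.5, 1, 20))
        cloud = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=-1)
        frac = coverage_fraction(elem, cloud, 0.03)
        assert 0.45 <= frac <= 0.55

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            coverage_fraction(_flat_element(), np.zeros((1, 3)), 0.0)


class TestClassify:
    def _setup(self, covered_elements, radius=0.25, **kwargs):
        grid = cylinder_grid(radius=10.0, n=5, m=36)
        mesh = QuadMesh(5, 36)
        nodes = grid.nodes(0)
        cloud = []
        elem_nodes = mesh.element_nodes(nodes)
        from aaastrain.averaging import shape_functions

        rng = np.random.default_rng(0)
        for e in covered_elements:
            r, s = rng.uniform(-1, 1, (2, 400))
            w = shape_functions(r, s)
            cloud.append(np.einsum("pa,ac->pc", w, elem_nodes[e]))
        cloud = np.concatenate(cloud) if cloud else np.empty((0, 3))
        return mesh, nodes, cloud

    def test_fully_covered_isolated_element_is_calcified(self):
        mesh, nodes, cloud = self._setup([40])
        labels = classify_elements(mesh, nodes, cloud, capture_radius=0.3)
        assert labels.calcified[40]
        assert labels.coverage[40] > 0.9

    def test_all_zero_coverage_gives_no_calcified(self):
        mesh, nodes, _ = self._setup([])
        labels = classify_elements(mesh, nodes, None)
        assert labels.calcified.sum() == 0

    def test_below_half_coverage_is_non_calcified(self):
        labels = ElementLabels(np.array([0.4]), np.array([0.4]) >= 0.5)
        assert not labels.calcified[0]
        mesh, nodes, cloud = self._setup([40])
        # shrink the capture radius so only part of the element sees points
        lab = classify_elements(mesh, nodes, cloud, threshold=0.999, capture_radius=0.05)
        assert not lab.calcified.all()

    def test_small_patches_cleared_by_min_patch_elements(self):
        mesh, nodes, cloud = self._setup([40, 41, 42, 100])  # run of 3 + isolated 1
        labels = classify_elements(mesh, nodes, cloud, capture_radius=0.3, min_patch_elements=2)
        assert labels.calcified[[40, 41, 42]].all()
        assert not labels.calcified[100]

    def test_invariant_to_calcification_point_order(self):
        mesh, nodes, cloud = self._setup([10, 50, 90])
        rng = np.random.default_rng(5)
        shuffled = cloud[rng.permutation(len(cloud))]
        a = classify_elements(mesh, nodes, cloud, capture_radius=0.3)
        b = classify_elements(mesh, nodes, shuffled, capture_radius=0.3)
        np.testing.assert_array_equal(a.calcified, b.calcified)
        np.testing.assert_allclose(a.coverage, b.coverage, atol=1e-12)


def _amp_field(values_pct, valid=None):
    amp = np.stack([np.asarray(values_pct), np.asarray(values_pct)], axis=-1) / 100.0
    v = np.ones(len(values_pct), bool) if valid is None else valid
    return AmplitudeField(amp, v)


class TestDistributionIndices:
    def test_hand_computed_example(self):
        # {1,2,3,4}%: mean 2.5, max 4, ratio 1.6, heterogeneity 0.5164 (sd n-1)
        amp = _amp_field([1.0, 2.0, 3.0, 4.0])
        labels = ElementLabels(np.zeros(4), np.zeros(4, bool))
        rep = distribution_indices(amp, labels)
        r = rep.indices["circumferential"]["non_calcified"]
        assert np.isclose(r["mean_pct"], 2.5)
        assert np.isclose(r["max_pct"], 4.0)
        assert np.isclose(r["strain_ratio"], 1.6)
        assert np.isclose(r["heterogeneity"], 1.2909944 / 2.5, atol=1e-6)
        assert np.isclose(r["median_pct"], 2.5)

    def test_constant_amplitudes(self):
        amp = _amp_field([2.0, 2.0, 2.0])
        rep = distribution_indices(amp, ElementLabels(np.zeros(3), np.zeros(3, bool)))
        r = rep.indices["longitudinal"]["non_calcified"]
        assert r["strain_ratio"] == 1.0
        assert r["heterogeneity"] == 0.0

    def test_single_element_region(self):
        amp = _amp_field([2.0, 3.0])
        labels = ElementLabels(np.array([1.0, 0.0]), np.array([True, False]))
        rep = distribution_indices(amp, labels)
        r = rep.indices["circumferential"]["calcified"]
        assert r["n_elements"] == 1
        assert r["strain_ratio"] == 1.0
        assert r["heterogeneity"] is None  # sd needs n >= 2

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.5, 3.0, 40)
        labels = ElementLabels(np.zeros(40), rng.uniform(size=40) < 0.3)
        a = distribution_indices(_amp_field(vals), labels)
        b = distribution_indices(_amp_field(vals * 3.0), labels)
        for region in ("calcified", "non_calcified"):
            ra = a.indices["circumferential"][region]
            rb = b.indices["circumferential"][region]
            assert np.isclose(rb["mean_pct"], 3 * ra["mean_pct"])
            assert np.isclose(rb["max_pct"], 3 * ra["max_pct"])
            assert np.isclose(rb["strain_ratio"], ra["strain_ratio"])
            assert np.isclose(rb["heterogeneity"], ra["heterogeneity"])

    def test_invalid_elements_excluded(self):
        valid = np.array([True, True, False])
        amp = _amp_field([1.0, 2.0, 100.0], valid)
        rep = distribution_indices(amp, ElementLabels(np.zeros(3), np.zeros(3, bool)))
        assert rep.n_excluded == 1
        assert rep.indices["circumferential"]["non_calcified"]["max_pct"] == 2.0


def exact_left_p(x, y):
    """Enumeration oracle: P(U_x <= u_obs) over all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(
            1.0 if a < b else (0.5 if a == b else 0.0)
            for a in sample_x for b in sample_y
        )

    # left-tailed: small U_x (x below y gives LARGE... use scipy's convention)
    u_obs = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys)
        if u <= u_obs:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mannwhitney_left([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert np.isclose(res.p_value, 0.05)
        assert np.isclose(res.p_value, exact_left_p([1, 2, 3], [4, 5, 6]))
        assert res.u_statistic == 0.0
        assert res.stars == ""

    def test_reversed_samples_p_one(self):
        res = mannwhitney_left([4, 5, 6], [1, 2, 3])
        assert np.isclose(res.p_value, 1.0)
        assert np.isclose(res.p_value, exact_left_p([4, 5, 6], [1, 2, 3]))

    def test_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = list(np.round(rng.normal(size=4), 3))
            y = list(np.round(rng.normal(0.5, 1, size=5), 3))
            res = mannwhitney_left(x, y)
            assert np.isclose(res.p_value, exact_left_p(x, y), atol=1e-12)

    def test_ties_switch_to_asymptotic(self):
        res = mannwhitney_left([1, 2, 2], [2, 3, 4])
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(10)
        res = mannwhitney_left(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mannwhitney_left([], [1.0])

    def test_stars_thresholds(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"


class TestKSNormality:
    def test_gaussian_rarely_rejected(self):
        rng = np.random.default_rng(12)
        outcomes = [ks_normality(rng.normal(3.0, 1.5, size=300))[0] for _ in range(30)]
        assert np.mean(outcomes) >= 0.9

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(13)
        ok, stat, p = ks_normality(rng.lognormal(0.0, 1.0, size=500))
        assert not ok and p < 0.001

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1.0, 2.0, 3.0])
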