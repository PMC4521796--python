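"""Poisson intensity fitting, K diagnostics, NN metrics, permutation test."""

import numpy as np
import pandas as pd
import pytest

from retmap.geometry import CapWindow
from retmap.pointprocess import (
    PointPattern,
    PoissonIntensityModel,
    _quadrature,
    csr_envelope,
    k_function,
    nn_distances,
    relative_density_map,
    simulate_csr,
    simulate_poisson,
    within_eye_permutation_test,
)


@pytest.fixture(scope="module")
def csr100(window):
    return simulate_csr(100, window, seed=1)


class TestIntensityFit:
    def test_quadrature_weights_sum_to_window_area(self, csr100, window):
        _, _, w, _ = _quadrature(csr100)
        assert w.sum() == pytest.approx(window.planar_area, rel=1e-3)

    def test_homogeneous_mle_identity(self, window):
        # degree-0 fit is exactly log(n / |W|) for any pattern
        for seed, n in ((1, 100), (2, 37), (3, 250)):
            pat = simulate_csr(n, window, seed=seed)
            res = PoissonIntensityModel(pat, degree=0).fit()
            assert res.coefficients[0] == pytest.approx(np.log(n / window.planar_area), abs=1e-8)

    def test_loglik_nondecreasing_in_degree(self, csr100):
        lls = [PoissonIntensityModel(csr100, degree=d).fit().loglik for d in (0, 1, 2, 3)]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_loglinear_recovery_single_fit(self, window):
        b0, b1 = np.log(0.01), 0.02
        pat = simulate_poisson(lambda x, y: np.exp(b0 + b1 * np.asarray(x)), window, seed=7)
        res = PoissonIntensityModel(pat, degree=1).fit()
        assert res.coefficients[1] == pytest.approx(b1, abs=3 * res.bse[1])

    def test_too_few_points_rejected(self, window):
        pat = simulate_csr(3, window, seed=1)
        with pytest.raises(ValueError):
            PoissonIntensityModel(pat, degree=2)
        with pytest.raises(ValueError):
            PoissonIntensityModel(pat, degree=-1)

    def test_marked_fit_splits_by_level(self, csr100):
        marks = pd.DataFrame({"grp": ["a"] * 60 + ["b"] * 40})
        pat = PointPattern(csr100.x, csr100.y, marks, csr100.window)
        res = PoissonIntensityModel(pat, degree=0, mark="grp").fit()
        assert set(res.levels) == {"a", "b"}
        la = res.levels["a"].coefficients[0]
        assert la == pytest.approx(np.log(60 / pat.window.planar_area), abs=1e-8)
        assert res.loglik == pytest.approx(sum(r.loglik for r in res.levels.values()))

    def test_expected_count_matches_n_for_mle(self, csr100):
        res = PoissonIntensityModel(csr100, degree=2).fit()
        # Poisson MLE conserves the total count (up to quadrature error)
        assert res.expected_count() == pytest.approx(len(csr100), rel=0.02)

    def test_summary_mentions_terms(self, csr100):
        res = PoissonIntensityModel(csr100, degree=1).fit()
        s = res.summary()
        assert "log-likelihood" in s and "x" in s and "y" in s


class TestSimulation:
    def test_mean_count_matches_integral(self, window):
        lam = 50 / window.planar_area
        counts = [
            len(simulate_poisson(lambda x, y: np.full(np.shape(x), lam), window, seed=s))
            for s in range(300)
        ]
        se = np.sqrt(50 / 300)
        assert np.mean(counts) == pytest.approx(50, abs=4 * se)

    def test_zero_intensity_gives_empty_pattern(self, window):
        pat = simulate_poisson(lambda x, y: np.zeros(np.shape(x)), window, seed=1)
        assert len(pat) == 0

    def test_seed_determinism(self, window):
        f = lambda x, y: np.full(np.shape(x), 0.005)  # noqa: E731
        a = simulate_poisson(f, window, seed=42)
        b = simulate_poisson(f, window, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestKFunction:
    def test_two_point_estimator_definition(self, window):
        pat = PointPattern([0.0, 10.0], [0.0, 0.0], window=window)
        res = k_function(pat, r_grid=np.array([5.0, 10.0, 20.0]), correction="none")
        assert res.k[0] == 0
        assert res.k[1] == pytest.approx(window.planar_area)
        assert res.k[2] == pytest.approx(window.planar_area)

    def test_nondecreasing_and_theoretical_reference(self, csr100):
        res = k_function(csr100)
        assert np.all(np.diff(res.k) >= 0)
        assert res.theoretical == pytest.approx(np.pi * res.r**2)

    def test_clustered_pattern_exceeds_envelope_at_small_r(self, window):
        rng = np.random.default_rng(5)
        # parent-offspring: tight daughters around 12 parents
        px = rng.uniform(-30, 30, 12)
        py = rng.uniform(-30, 30, 12)
        x = np.repeat(px, 15) + rng.normal(0, 1.5, 180)
        y = np.repeat(py, 15) + rng.normal(0, 1.5, 180)
        keep = np.hypot(x, y) <= window.radius
        pat = PointPattern(x[keep], y[keep], window=window)
        r, lo, hi, _ = csr_envelope(pat, n_sim=39, seed=2)
        small = (r > 0) & (r <= 10)
        assert np.all(k_function(pat, r).k[small] > hi[small])

    def test_single_point_rejected(self, window):
        with pytest.raises(ValueError):
            k_function(PointPattern([0.0], [0.0], window=window))


class TestEnvelope:
    def test_single_simulation_envelope_is_that_curve(self, csr100):
        r, lo, hi, sims = csr_envelope(csr100, n_sim=1, seed=9)
        assert np.array_equal(lo, hi)
        assert np.array_equal(lo, sims[0])

    def test_reproducible(self, csr100):
        _, lo1, hi1, _ = csr_envelope(csr100, n_sim=9, seed=3)
        _, lo2, hi2, _ = csr_envelope(csr100, n_sim=9, seed=3)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)


class TestNNDistances:
    def test_great_circle_never_exceeds_projected(self, csr100):
        g = nn_distances(csr100, "great_circle")
        e = nn_distances(csr100, "projected_euclidean")
        assert np.all(g <= e + 1e-9)

    def test_geometry_module_oracle_pair(self, window):
        # retinal points (30,0) and (30,90): chord 42.43, arc 41.41
        pat = PointPattern([0.0, 30.0], [30.0, 0.0], window=window)
        e = nn_distances(pat, "projected_euclidean")
        g = nn_distances(pat, "great_circle")
        assert e[0] == pytest.approx(30 * np.sqrt(2), abs=1e-9)
        assert g[0] == pytest.approx(np.degrees(np.arccos(0.75)), abs=1e-9)

    def test_fovea_point_metrics_agree(self, window):
        pat = PointPattern([0.0, 20.0], [0.0, 10.0], window=window)
        e = nn_distances(pat, "projected_euclidean")
        g = nn_distances(pat, "great_circle")
        assert g[0] == pytest.approx(e[0], abs=1e-9)

    def test_single_point_rejected(self, window):
        with pytest.raises(ValueError):
            nn_distances(PointPattern([0.0], [0.0], window=window))


def _pattern_with_eyes(window, seed, sizes=(2, 2, 3), n=60):
    rng = np.random.default_rng(seed)
    pat = simulate_csr(n, window, seed=rng.integers(2**31))
    eye = np.array([f"s{i}" for i in range(n)], dtype=object)
    pick = rng.choice(n, size=sum(sizes), replace=False)
    out = 0
    for g, s in enumerate(sizes):
        eye[pick[out : out + s]] = f"m{g}"
        out += s
    return PointPattern(pat.x, pat.y, pd.DataFrame({"eye_id": eye}), window)


class TestPermutationTest:
    def test_p_value_formula_extreme_observation(self, window):
        # one multiplet pushed to near-antipodal separation inside a tight
        # background cluster: the observed statistic exceeds every null draw
        rng = np.random.default_rng(0)
        bx = rng.uniform(-5, 5, 200)
        by = rng.uniform(-5, 5, 200)
        x = np.concatenate([[0.0, 0.0], bx])
        y = np.concatenate([[59.0, -59.0], by])
        eyes = ["m0", "m0"] + [f"s{i}" for i in range(200)]
        pat = PointPattern(x, y, pd.DataFrame({"eye_id": eyes}), window)
        res = within_eye_permutation_test(pat, B=999, seed=1)
        assert res.observed > res.null.max()
        assert res.p_value == pytest.approx(1 / 1000)

    def test_errors(self, window):
        pat = _pattern_with_eyes(window, 1)
        with pytest.raises(ValueError):
            within_eye_permutation_test(pat, B=0, seed=1)
        singles = PointPattern(
            pat.x, pat.y, pd.DataFrame({"eye_id": [f"s{i}" for i in range(len(pat))]}), window
        )
        with pytest.raises(ValueError):
            within_eye_permutation_test(singles, B=9, seed=1)

    def test_null_p_not_systematically_small(self, window):
        ps = [
            within_eye_permutation_test(_pattern_with_eyes(window, s), B=99, seed=s).p_value
            for s in range(40)
        ]
        # under the null the p-value is (super-)uniform
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.15
        assert np.mean(ps) > 0.3


class TestRelativeDensity:
    def test_colocated_points_concentrate_mass(self, window):
        pat = PointPattern(np.full(30, 20.0), np.full(30, 10.0), window=window)
        gx, gy, ratio = relative_density_map(pat, bandwidth=5.0)
        at = np.nanargmin((gx - 20) ** 2 + (gy - 10) ** 2)
        far = np.nanargmin((gx + 40) ** 2 + (gy + 20) ** 2)
        assert ratio.ravel()[at] > 10
        assert ratio.ravel()[far] < 0.5

    def test_invalid_bandwidth_rejected(self, csr100):
        with pytest.raises(ValueError):
            relative_density_map(csr100, bandwidth=0)

    def test_flat_for_csr(self, window):
        pat = simulate_csr(2000, window, seed=4)
        _, _, ratio = relative_density_map(pat, bandwidth=10.0)
        assert 0.9 <= np.nanmean(ratio) <= 1.1
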