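"""Geographic distances, IBD regression and Mantel tests."""

import math

import numpy as np
import pytest

from popgenflow.errors import DataError
from popgenflow.io import PopulationMetadata
from popgenflow.simulate import STUDY_METADATA
from popgenflow.spatial import (
    EARTH_RADIUS_KM,
    covariate_matrix,
    haversine_km,
    haversine_matrix,
    ibd_regression,
    mantel_test,
)


class TestHaversine:
    def test_identical_coordinates_zero(self):
        assert haversine_km(100.0, 20.0, 100.0, 20.0) == 0.0

    def test_antipodal_half_circumference(self):
        assert haversine_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9)

    def test_against_spherical_law_of_cosines(self):
        # GZ and NN coordinates; independent second formula as oracle
        lon1, lat1 = map(math.radians, (113.27, 23.13))
        lon2, lat2 = map(math.radians, (108.37, 22.82))
        expect = EARTH_RADIUS_KM * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1))
        assert haversine_km(113.27, 23.13, 108.37, 22.82) == pytest.approx(expect, rel=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(DataError):
            PopulationMetadata("bad", 200.0, 0.0, 0.0, 0.0, 0.0)


class TestCovariateMatrix:
    def test_elevation_difference(self):
        mat = covariate_matrix(STUDY_METADATA, "elevation_m")
        i, j = mat.codes.index("BS"), mat.codes.index("GZ")
        assert mat.values[i, j] == pytest.approx(1660.0)

    def test_symmetric_zero_diagonal_all_covariates(self):
        for name in ("geographic_km", "elevation_m", "aap_mm", "aat_c"):
            mat = covariate_matrix(STUDY_METADATA, name)
            assert np.allclose(mat.values, mat.values.T)
            assert not np.diag(mat.values).any()
            assert (mat.values >= 0).all()

    def test_unknown_covariate(self):
        with pytest.raises(DataError):
            covariate_matrix(STUDY_METADATA, "soil_ph")


def _line_matrices(a, b, n=8, seed=0):
    """Fst matrix lying exactly on Fst/(1-Fst) = a + b ln(km)."""
    rng = np.random.default_rng(seed)
    geo = np.zeros((n, n))
    fst = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            km = float(rng.uniform(50, 2000))
            y = a + b * math.log(km)
            geo[i, j] = geo[j, i] = km
            fst[i, j] = fst[j, i] = y / (1 + y)
    return fst, geo


class TestIBDRegression:
    def test_recovers_synthetic_line(self):
        fst, geo = _line_matrices(0.0534, 0.0034)
        res = ibd_regression(fst, geo, n_perm=0)
        assert res.intercept == pytest.approx(0.0534, abs=1e-12)
        assert res.slope == pytest.approx(0.0034, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_fst_zero_slope(self):
        n = 6
        geo = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 100.0
        fst = np.full((n, n), 0.2)
        np.fill_diagonal(fst, 0.0)
        res = ibd_regression(fst, geo, n_perm=0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_complete_differentiation_pairs_excluded(self):
        fst, geo = _line_matrices(0.05, 0.003)
        fst[0, 1] = fst[1, 0] = 1.0
        res = ibd_regression(fst, geo, n_perm=0)
        assert res.excluded_pairs == 1
        assert res.n_pairs == 8 * 7 // 2 - 1

    def test_scale_equivariance(self):
        fst, geo = _line_matrices(0.02, 0.01, seed=3)
        r1 = ibd_regression(fst, geo, n_perm=0)
        r2 = ibd_regression(fst, geo * 7.0, n_perm=0)
        assert r2.slope == pytest.approx(r1.slope, abs=1e-10)
        assert r2.intercept == pytest.approx(r1.intercept - r1.slope * math.log(7.0),
                                             abs=1e-10)

    def test_too_few_usable_pairs(self):
        fst = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        geo = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        with pytest.raises(DataError):
            ibd_regression(fst, geo, n_perm=0)


class TestMantel:
    def test_self_correlation(self):
        _, geo = _line_matrices(0.05, 0.003)
        res = mantel_test(geo, geo, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_upper == pytest.approx(1 / 100)

    def test_negated_matrix(self):
        _, geo = _line_matrices(0.05, 0.003)
        res = mantel_test(geo, -geo, n_perm=49, seed=1)
        assert res.r == pytest.approx(-1.0)

    def test_constant_matrix_rejected(self):
        geo = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(DataError):
            mantel_test(geo * 0.0, geo, n_perm=9)

    def test_invariant_under_joint_relabeling(self):
        fst, geo = _line_matrices(0.05, 0.003, seed=5)
        perm = np.random.default_rng(0).permutation(fst.shape[0])
        r1 = mantel_test(geo, fst, n_perm=0 + 49, seed=9).r
        r2 = mantel_test(geo[np.ix_(perm, perm)], fst[np.ix_(perm, perm)],
                         n_perm=49, seed=9).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_p_roughly_uniform_for_independent_matrices(self):
        rng = np.random.default_rng(17)
        ps = []
        for rep in range(150):
            n = 7
            a = rng.random((n, n))
            b = rng.random((n, n))
            a = (a + a.T) / 2
            b = (b + b.T) / 2
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            ps.append(mantel_test(a, b, n_perm=49, seed=rep).p_upper)
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps <= 0.1).mean() < 0.25
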