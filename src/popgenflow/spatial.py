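"""Geographic/covariate distances, isolation-by-distance regression, Mantel tests.

Isolation by distance is tested through the linearized regression
``Fst/(1-Fst) = a + b ln(distance)`` with distances in km (natural log);
pairs with complete differentiation (Fst = 1) are excluded from the
linearized fit but retained for the Pearson correlation on raw Fst.
Significance of both the slope and the Pearson correlation comes from
Mantel permutations (joint row/column relabeling of one matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differentiation import PairwiseFstMatrix
from .errors import DataError
from .io import PopulationMetadata

EARTH_RADIUS_KM = 6371.0

_COVARIATES = {"elevation_m": "elevation", "aap_mm": "aap", "aat_c": "aat"}


@dataclass
class CovariateDistanceMatrix:
    codes: list[str]
    values: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T) or np.diag(self.values).any():
            raise DataError("covariate distance matrix must be symmetric, zero diagonal")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.codes, columns=self.codes)


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance (km) between two points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(meta: list[PopulationMetadata]) -> CovariateDistanceMatrix:
    """Pairwise great-circle distances between population coordinates."""
    P = len(meta)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            out[i, j] = out[j, i] = haversine_km(
                meta[i].longitude, meta[i].latitude,
                meta[j].longitude, meta[j].latitude)
    return CovariateDistanceMatrix([m.code for m in meta], out, "geographic_km")


def covariate_matrix(meta: list[PopulationMetadata], name: str) -> CovariateDistanceMatrix:
    """Absolute pairwise differences |x_i - x_j| of one covariate."""
    if name == "geographic_km":
        return haversine_matrix(meta)
    if name not in _COVARIATES:
        raise DataError(f"unknown covariate {name!r}; choose from "
                        f"{['geographic_km', *_COVARIATES]}")
    x = np.array([getattr(m, _COVARIATES[name]) for m in meta], dtype=float)
    if np.isnan(x).any():
        raise DataError(f"covariate {name!r} has missing values")
    out = np.abs(x[:, None] - x[None, :])
    return CovariateDistanceMatrix([m.code for m in meta], out, name)


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


@dataclass
class MantelResult:
    r: float
    p_upper: float
    p_lower: float
    n_perm: int


def mantel_test(x, y, n_perm: int = 9999, seed: int | None = None) -> MantelResult:
    """Mantel permutation test of the correlation between two distance matrices.

    Pearson r over upper-triangle pairs; one matrix's labels are permuted
    jointly over rows and columns.  ``p_upper`` is the upper-tail (r_perm >=
    r_obs) p-value, ``p_lower`` the lower tail; both use (r+1)/(n+1).
    """
    xm = x.values if isinstance(x, CovariateDistanceMatrix) else np.asarray(x, float)
    ym = y.values if isinstance(y, CovariateDistanceMatrix) else np.asarray(y, float)
    if isinstance(x, CovariateDistanceMatrix) and isinstance(y, CovariateDistanceMatrix):
        if x.codes != y.codes:
            raise DataError("Mantel: matrices must share population labels")
    if xm.shape != ym.shape or xm.shape[0] != xm.shape[1]:
        raise DataError("Mantel: matrices must be square and conformable")
    xv = _offdiag(xm)
    if np.std(xv) == 0 or np.std(_offdiag(ym)) == 0:
        raise DataError("Mantel: constant distance matrix, correlation undefined")
    r_obs = float(np.corrcoef(xv, _offdiag(ym))[0, 1])
    rng = np.random.default_rng(seed)
    up = lo = 1
    for _ in range(n_perm):
        perm = rng.permutation(xm.shape[0])
        r_p = float(np.corrcoef(xv, _offdiag(ym[np.ix_(perm, perm)]))[0, 1])
        if r_p >= r_obs - 1e-12:
            up += 1
        if r_p <= r_obs + 1e-12:
            lo += 1
    return MantelResult(r_obs, up / (n_perm + 1), lo / (n_perm + 1), n_perm)


@dataclass
class IBDResult:
    intercept: float
    slope: float
    r_squared: float
    p_slope: float | None
    pearson_r: float
    p_pearson: float | None
    n_pairs: int
    excluded_pairs: int
    n_perm: int


def _linearized_fit(fst: np.ndarray, geo: np.ndarray):
    """OLS of Fst/(1-Fst) on ln(km) over usable off-diagonal pairs."""
    iu = np.triu_indices(fst.shape[0], 1)
    f, g = fst[iu], geo[iu]
    usable = (f < 1.0) & (g > 0.0)
    n_excl = int((~usable).sum())
    if usable.sum() < 3:
        raise DataError("IBD regression needs >= 3 pairs with Fst < 1, distance > 0")
    y = f[usable] / (1.0 - f[usable])
    x = np.log(g[usable])
    res = stats.linregress(x, y)
    r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 0.0  # constant y
    return res.intercept, res.slope, r2, int(usable.sum()), n_excl


def ibd_regression(
    fst: PairwiseFstMatrix | np.ndarray,
    geo: CovariateDistanceMatrix | np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> IBDResult:
    """Isolation-by-distance: Fst/(1-Fst) ~ a + b ln(distance km).

    The slope p-value is a two-sided Mantel permutation test (|b_perm| >=
    |b_obs| under joint relabeling of the Fst matrix); the Pearson test on
    raw Fst vs distance, which tolerates Fst = 1 pairs, reports the
    upper-tail Mantel p.
    """
    fm = fst.values if isinstance(fst, PairwiseFstMatrix) else np.asarray(fst, float)
    gm = geo.values if isinstance(geo, CovariateDistanceMatrix) else np.asarray(geo, float)
    if isinstance(fst, PairwiseFstMatrix) and isinstance(geo, CovariateDistanceMatrix):
        if fst.codes != geo.codes:
            raise DataError("IBD: Fst and distance matrices must share labels")
    a, b, r2, n_pairs, n_excl = _linearized_fit(fm, gm)

    p_slope = p_pearson = None
    pearson_r = float(np.corrcoef(_offdiag(gm), _offdiag(fm))[0, 1])
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_b = hits_r = 1
        for _ in range(n_perm):
            perm = rng.permutation(fm.shape[0])
            fp = fm[np.ix_(perm, perm)]
            try:
                _, b_p, *_ = _linearized_fit(fp, gm)
            except DataError:
                continue
            if abs(b_p) >= abs(b) - 1e-12:
                hits_b += 1
            r_p = float(np.corrcoef(_offdiag(gm), _offdiag(fp))[0, 1])
            if r_p >= pearson_r - 1e-12:
                hits_r += 1
        p_slope = hits_b / (n_perm + 1)
        p_pearson = hits_r / (n_perm + 1)
    return IBDResult(a, b, r2, p_slope, pearson_r, p_pearson, n_pairs, n_excl, n_perm)
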