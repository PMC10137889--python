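"""Population differentiation: AMOVA phi_st, pairwise phi_st, and Gst/Nst.

AMOVA partitions squared molecular distances into among- and within-
population variance components (Excoffier-style sums of squares).  For
aligned haploid sequences the number of pairwise nucleotide differences is
itself the squared Euclidean distance between sequences, so difference
counts enter the sums of squares as-is; set ``square_distances=True`` when
supplying raw (unsquared) distances.

Gst and Nst follow the equal-population-weight unbiased estimators of Pons &
Petit: Gst contrasts unordered haplotype diversities (hS within vs hT
total), Nst the ordered analogues in which haplotype pairs are weighted by
their mutational distance.  Nst significantly greater than Gst indicates
phylogeographic structure (closely related haplotypes co-occur).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .io import HaplotypeTable, PairwiseDifferenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    n_perm: int

    def as_table(self) -> pd.DataFrame:
        """Table-style AMOVA report (source, d.f., SS, variance, %)."""
        return pd.DataFrame(
            {
                "source": ["Among populations", "Within populations", "Total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "sum_of_squares": [self.ss_among, self.ss_within, self.ss_total],
                "variance_component": [
                    self.sigma2_among,
                    self.sigma2_within,
                    self.sigma2_among + self.sigma2_within,
                ],
                "pct_variance": [self.pct_among, self.pct_within, 100.0],
                "phi_st": [self.phi_st, np.nan, np.nan],
                "p_value": [self.p_value if self.p_value is not None else np.nan,
                            np.nan, np.nan],
            }
        )


def _amova_components(d2: np.ndarray, labels: np.ndarray, pops: np.ndarray):
    """Variance components from a squared-distance matrix and labels."""
    N = d2.shape[0]
    P = pops.size
    ss_total = float(np.triu(d2, 1).sum()) / N
    ss_within = 0.0
    sizes = np.empty(P)
    for k, p in enumerate(pops):
        idx = np.flatnonzero(labels == p)
        sizes[k] = idx.size
        if idx.size == 0:
            raise DataError(f"population {p!r} has no samples")
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, 1).sum()) / idx.size
    ss_among = ss_total - ss_within
    df_among = P - 1
    df_within = N - P
    if df_within <= 0:
        raise DataError("AMOVA requires N > number of populations")
    sigma2_w = ss_within / df_within
    n_c = (N - float(np.sum(sizes**2)) / N) / df_among
    sigma2_a = (ss_among / df_among - sigma2_w) / n_c
    return ss_total, ss_within, ss_among, sigma2_a, sigma2_w, df_among, df_within


def _phi(sigma2_a: float, sigma2_w: float) -> float:
    tot = sigma2_a + sigma2_w
    if tot == 0.0:
        return 0.0
    return sigma2_a / tot


def amova(
    d: PairwiseDifferenceMatrix | np.ndarray,
    pops=None,
    n_perm: int = 9999,
    seed: int | None = None,
    square_distances: bool = False,
    clamp_negative: bool = False,
) -> AMOVAResult:
    """One-level AMOVA (among vs within populations) with a permutation test.

    Parameters
    ----------
    d
        Pairwise difference matrix (or raw square matrix with ``pops``).
        Entries are treated as squared molecular distances.
    pops
        Per-sample population labels; taken from ``d.populations`` when a
        :class:`PairwiseDifferenceMatrix` carries them.
    n_perm
        Label permutations for the phi_st test; 0 skips the test.
    clamp_negative
        Truncate a negative among-population variance component at 0
        instead of retaining it.

    The permutation p-value uses the (r+1)/(n+1) convention, the observed
    configuration counting as one replicate.
    """
    if isinstance(d, PairwiseDifferenceMatrix):
        mat = np.asarray(d.d, dtype=float)
        if pops is None:
            pops = d.populations
    else:
        mat = np.asarray(d, dtype=float)
    if pops is None:
        raise DataError("population labels required")
    labels = np.asarray(pops)
    if labels.size != mat.shape[0]:
        raise DataError("one population label per sample required")
    if labels.size < 3:
        raise DataError("AMOVA requires N >= 3 samples")
    d2 = mat**2 if square_distances else mat
    upops = pd.unique(labels)
    if upops.size < 2:
        raise DataError("AMOVA requires >= 2 populations")

    ss_t, ss_w, ss_a, s2a, s2w, dfa, dfw = _amova_components(d2, labels, upops)
    if s2a + s2w == 0.0:
        logger.warning("AMOVA: zero total variance; phi_st reported as 0")
    if clamp_negative and s2a < 0.0:
        s2a = 0.0
    phi = _phi(s2a, s2w)
    tot = s2a + s2w
    pct_a = 100.0 * s2a / tot if tot else 0.0

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 1  # the observed configuration
        for _ in range(n_perm):
            perm = labels[rng.permutation(labels.size)]
            *_, ps2a, ps2w, _, _ = _amova_components(d2, perm, upops)
            if clamp_negative and ps2a < 0.0:
                ps2a = 0.0
            if _phi(ps2a, ps2w) >= phi - 1e-12:
                hits += 1
        p_value = hits / (n_perm + 1)

    return AMOVAResult(dfa, dfw, ss_a, ss_w, ss_t, s2a, s2w,
                       pct_a, 100.0 - pct_a, phi, p_value, n_perm)


@dataclass
class PairwiseFstMatrix:
    """Symmetric matrix of pairwise phi_st between populations."""

    codes: list[str]
    values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.codes, columns=self.codes)


def pairwise_phist(
    d: PairwiseDifferenceMatrix | np.ndarray,
    pops=None,
    n_perm: int = 0,
    seed: int | None = None,
) -> PairwiseFstMatrix:
    """Two-population AMOVA phi_st for every population pair.

    Negative estimates are retained (not clamped), as in distance-based
    Fst software; callers may truncate for display.
    """
    if isinstance(d, PairwiseDifferenceMatrix):
        mat = np.asarray(d.d, dtype=float)
        if pops is None:
            pops = d.populations
    else:
        mat = np.asarray(d, dtype=float)
    labels = np.asarray(pops)
    codes = list(pd.unique(labels))
    P = len(codes)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            idx = np.flatnonzero(np.isin(labels, [codes[i], codes[j]]))
            res = amova(mat[np.ix_(idx, idx)], labels[idx], n_perm=n_perm,
                        seed=None if seed is None else seed + 1000 * i + j)
            out[i, j] = out[j, i] = res.phi_st
    return PairwiseFstMatrix(codes, out)


@dataclass
class GstNstResult:
    hS: float
    hT: float
    vS: float
    vT: float
    Gst: float
    Nst: float
    p_nst_gt_gst: float | None
    n_perm: int


def _pons_petit(counts: np.ndarray, dist: np.ndarray) -> tuple[float, float, float, float]:
    """Equal-weight unbiased within/total diversities, unordered and ordered.

    ``counts`` is (haplotype x population).  Returns (hS, hT, vS, vT).
    """
    n_k = counts.sum(axis=0).astype(float)
    P = counts.shape[1]
    freqs = counts / n_k  # p_ki, columns are populations
    corr = n_k / (n_k - 1.0)
    h_k = corr * (1.0 - np.sum(freqs**2, axis=0))
    v_k = corr * np.einsum("ik,jk,ij->k", freqs, freqs, dist)
    hS = float(h_k.mean())
    vS = float(v_k.mean())
    pbar = freqs.mean(axis=1)
    n_harm = P / np.sum(1.0 / n_k)
    hT = float(1.0 - np.sum(pbar**2) + hS / (n_harm * P))
    vT = float(pbar @ dist @ pbar + vS / (n_harm * P))
    return hS, hT, vS, vT


def gst_nst(
    h: HaplotypeTable,
    hap_dist: np.ndarray | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> GstNstResult:
    """Gst and Nst with a permutation test of Nst > Gst.

    ``hap_dist`` defaults to Hamming distances over the segregating-site
    state-vectors.  The null distribution permutes haplotype identities in
    the distance matrix (which leaves Gst untouched), and the one-tailed
    p-value is the proportion of permuted Nst values >= the observed Nst,
    (r+1)/(n+1) convention.
    """
    counts = h.counts.to_numpy(dtype=float)
    n_k = counts.sum(axis=0)
    keep = n_k >= 2
    if keep.sum() < 2:
        raise DataError("Gst/Nst require >= 2 populations with n >= 2")
    if not keep.all():
        logger.info("gst_nst: dropping %d populations with n < 2", int((~keep).sum()))
        counts = counts[:, keep]
    if hap_dist is None:
        hap_dist = h.distance_matrix().astype(float)
    hap_dist = np.asarray(hap_dist, dtype=float)
    H = counts.shape[0]
    if hap_dist.shape != (H, H) or not np.allclose(hap_dist, hap_dist.T):
        raise DataError("hap_dist must be a symmetric haplotype x haplotype matrix")

    hS, hT, vS, vT = _pons_petit(counts, hap_dist)
    gst = 1.0 - hS / hT if hT > 0 else 0.0
    nst = 1.0 - vS / vT if vT > 0 else 0.0

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(H)
            pd_ = hap_dist[np.ix_(perm, perm)]
            _, _, pvS, pvT = _pons_petit(counts, pd_)
            pnst = 1.0 - pvS / pvT if pvT > 0 else 0.0
            if pnst >= nst - 1e-12:
                hits += 1
        p = hits / (n_perm + 1)
    return GstNstResult(hS, hT, vS, vT, gst, nst, p, n_perm)
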