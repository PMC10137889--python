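"""Neutrality tests and mismatch-distribution demography.

Tajima's D contrasts the pairwise-difference estimator of theta (k_hat) with
the segregating-sites estimator (S/a1), normalized by the standard constants;
values near zero are consistent with neutral, constant-size evolution, and
significantly negative values suggest expansion (or selection).

Fu's Fs asks whether the observed number of distinct haplotypes k_obs is
larger than the Ewens sampling formula predicts given theta = k_hat:
S' = Pr(K >= k_obs | theta), Fs = ln(S'/(1-S')).  Strongly negative Fs
(excess haplotypes) again indicates expansion.

The mismatch distribution is the histogram of pairwise difference counts.
Under a sudden expansion (size N0 -> N1 at mutational time tau = 2ut ago)
its expectation has a closed form mixing the stationary geometric spectrum
F_i(theta) = theta^i/(1+theta)^(i+1) with a Poisson wave centred near tau;
the model is fit by least squares (SSD) and tested with Harpending's
raggedness and parametric bootstrap p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .diversity import harmonic_number
from .errors import DataError
from .io import PairwiseDifferenceMatrix
from .simulate import two_epoch_pairwise_matrix


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 chain of constants from the sample size."""
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, n: int, k_hat: float) -> float:
    """Tajima's D from segregating sites, sample size and mean pairwise diffs."""
    if n < 4:
        raise DataError("Tajima's D requires n >= 4")
    if S < 1:
        raise DataError("Tajima's D is undefined when S = 0")
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k_hat - S / c["a1"]) / denom


def tajimas_d_pvalue(D: float, n: int) -> float:
    """Two-sided p for Tajima's D via the bounded-beta approximation.

    D is rescaled onto its attainable range [Dmin, Dmax] and compared with a
    beta law of mean 0 and variance 1 on that interval (the approximation of
    the statistic's null distribution commonly used by sequence-statistics
    software).
    """
    c = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Exact big-integer recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|,
    converted to logs at the end (safe for the sample sizes used here).
    """
    row = [1]
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return np.array([math.log(v) if v > 0 else -math.inf for v in row])


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """Pr(K = k) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise DataError("Ewens distribution requires theta > 0")
    logs = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_denom = np.sum(np.log(theta + np.arange(n)))
    logp = logs + k * math.log(theta) - log_denom
    p = np.exp(logp)
    return p / p.sum()


def fu_fs(n: int, k_obs: int, k_hat: float) -> float:
    """Fu's Fs: log-odds of observing >= k_obs haplotypes given theta = k_hat.

    Returns +/-inf at the boundaries (k_obs = 1 gives S' = 1, Fs = +inf),
    which callers should treat as flagged boundary values.
    """
    if n < 2 or not 1 <= k_obs <= n:
        raise DataError("Fu's Fs requires n >= 2 and 1 <= k_obs <= n")
    if k_hat <= 0:
        raise DataError("Fu's Fs is undefined when k_hat = 0")
    if k_obs == 1:
        return math.inf  # S' = Pr(K >= 1) = 1 exactly: boundary value
    p = ewens_k_distribution(n, k_hat)
    s_prime = float(p[k_obs:].sum())
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


@dataclass
class NeutralityResult:
    population: str
    tajima_d: float | None
    p_tajima: float | None
    fu_fs: float | None
    defined: bool = True


def neutrality_tests(population: str, S: int, n: int, k_hat: float,
                     k_obs: int) -> NeutralityResult:
    """Tajima's D (with beta-approximation p) and Fu's Fs for one population."""
    if S < 1 or n < 4:
        return NeutralityResult(population, None, None, None, defined=False)
    D = tajimas_d(S, n, k_hat)
    fs = fu_fs(n, k_obs, k_hat) if k_hat > 0 else None
    return NeutralityResult(population, D, tajimas_d_pvalue(D, n), fs)


# ---------------------------------------------------------------------------
# Mismatch distribution
# ---------------------------------------------------------------------------

def mismatch_observed(d: PairwiseDifferenceMatrix | np.ndarray) -> np.ndarray:
    """Normalized histogram of pairwise difference counts, classes 0..max."""
    mat = d.d if isinstance(d, PairwiseDifferenceMatrix) else np.asarray(d)
    n = mat.shape[0]
    if n < 2:
        raise DataError("mismatch distribution requires n >= 2")
    vals = mat[np.triu_indices(n, 1)]
    spectrum = np.bincount(vals.astype(int)) / vals.size
    return spectrum


def _stationary_spectrum(theta: float, i: np.ndarray) -> np.ndarray:
    # log-space form of theta^i / (1+theta)^(i+1); safe for large class counts
    return np.exp(i * math.log(theta) - (i + 1.0) * math.log1p(theta))


def expected_mismatch(theta0: float, theta1: float, tau: float,
                      classes: int) -> np.ndarray:
    """Expected pairwise-difference spectrum under sudden expansion.

    Derived from the two-epoch coalescent for a pair of lineages: with the
    coalescence time expressed in mutational units s = 2ut, the pair hazard
    is 1/theta1 for s < tau and 1/theta0 beyond, and the difference count is
    Poisson(s).  Integrating out s gives, for class i:

        F_i = F_i(theta1) * P[Gamma(i+1, 1 + 1/theta1) <= tau]
            + exp(-tau/theta1) * sum_{j<=i} Poisson(j; tau) * F_{i-j}(theta0)

    with F_i(theta) the stationary geometric spectrum.  tau = 0 with
    theta0 = theta1 reduces to the stationary form.
    """
    if min(theta0, theta1) < 0 or tau < 0:
        raise DataError("mismatch parameters must be non-negative")
    i = np.arange(classes)
    t1 = max(theta1, 1e-12)
    t0 = max(theta0, 1e-12)
    recent = _stationary_spectrum(t1, i) * stats.gamma.cdf(tau, a=i + 1,
                                                           scale=1.0 / (1.0 + 1.0 / t1))
    pois = stats.poisson.pmf(np.arange(classes), tau) if tau > 0 else \
        np.eye(1, classes)[0]
    anc = _stationary_spectrum(t0, i)
    ancient = np.array([np.sum(pois[: k + 1] * anc[: k + 1][::-1]) for k in i])
    return recent + math.exp(-tau / t1) * ancient


def raggedness(spectrum: np.ndarray) -> float:
    """Harpending's raggedness r = sum (x_i - x_{i-1})^2 with x_{d+1} = 0."""
    x = np.concatenate([np.asarray(spectrum, float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def _ssd(obs: np.ndarray, theta0: float, theta1: float, tau: float,
         renormalize: bool) -> float:
    exp = expected_mismatch(theta0, theta1, tau, obs.size)
    if renormalize:
        tot = exp.sum()
        if tot > 0:
            exp = exp / tot
    return float(np.sum((obs - exp) ** 2))


@dataclass
class MismatchFit:
    observed_spectrum: np.ndarray
    theta0: float
    theta1: float
    tau: float
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_rag: float | None = None
    n_boot: int = 0
    converged: bool = True
    expected_spectrum: np.ndarray = field(default=None, repr=False)


def _fit_sudden_expansion(obs: np.ndarray, renormalize: bool):
    """Coarse grid then Nelder-Mead polish of (theta0, theta1, tau) in log space."""
    d = obs.size - 1
    mean_k = float(np.sum(np.arange(obs.size) * obs))
    tau_grid = np.linspace(0.0, 2.0 * max(d, 1), 17)
    th1_grid = np.geomspace(1e-2, 10.0 * max(d, 1), 13)
    th0_grid = np.geomspace(1e-4, max(mean_k, 1.0), 7)
    best = (math.inf, (1e-3, 1.0, 0.0))
    for tau in tau_grid:
        for t1 in th1_grid:
            for t0 in th0_grid:
                ssd = _ssd(obs, t0, t1, tau, renormalize)
                if ssd < best[0]:
                    best = (ssd, (t0, t1, tau))

    def objective(logp):
        t0, t1, tau = np.exp(logp)
        return _ssd(obs, t0, t1, tau, renormalize)

    x0 = np.log(np.maximum(best[1], 1e-10))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14,
                                     "maxiter": 4000, "maxfev": 6000})
    t0, t1, tau = np.exp(res.x)
    ssd = float(res.fun)
    if ssd > best[0]:
        t0, t1, tau = best[1]
        ssd = best[0]
    return t0, t1, tau, ssd, bool(res.success or ssd <= best[0])


def fit_mismatch(observed_spectrum: np.ndarray, n_boot: int = 0,
                 seed: int | None = None, n: int | None = None,
                 renormalize: bool = True) -> MismatchFit:
    """Least-squares sudden-expansion fit with parametric-bootstrap p-values.

    ``n`` (the sample size behind the spectrum) is required when
    ``n_boot > 0``: each bootstrap replicate simulates a two-epoch coalescent
    sample of size n at the fitted parameters, refits it, and the p-values
    are the proportions of simulated SSD / raggedness >= the observed ones.

    By default the expected spectrum is renormalized over the observed
    classes (mass beyond the largest observed difference count is folded
    back), so SSD compares two unit-sum vectors.
    """
    obs = np.asarray(observed_spectrum, dtype=float)
    if obs.size < 2:
        raise DataError("mismatch fit requires >= 2 classes")
    t0, t1, tau, ssd, ok = _fit_sudden_expansion(obs, renormalize)
    rag = raggedness(obs)
    fit = MismatchFit(obs, t0, t1, tau, ssd, rag, n_boot=n_boot, converged=ok)
    exp = expected_mismatch(t0, t1, tau, obs.size)
    fit.expected_spectrum = exp / exp.sum() if renormalize and exp.sum() > 0 else exp

    if n_boot > 0:
        if n is None:
            raise DataError("parametric bootstrap requires the sample size n")
        rng = np.random.default_rng(seed)
        hits_ssd = hits_rag = 1
        for _ in range(n_boot):
            dmat = two_epoch_pairwise_matrix(n, t0, t1, tau, rng)
            spec = mismatch_observed(dmat)
            bt0, bt1, btau, bssd, _ = _fit_sudden_expansion(spec, renormalize)
            if bssd >= ssd - 1e-15:
                hits_ssd += 1
            if raggedness(spec) >= rag - 1e-15:
                hits_rag += 1
        fit.p_ssd = hits_ssd / (n_boot + 1)
        fit.p_rag = hits_rag / (n_boot + 1)
    return fit
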