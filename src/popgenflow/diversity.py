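"""Per-population diversity statistics: pi, Watterson's theta, haplotype diversity.

Definitions
-----------
* nucleotide diversity ``pi``: mean pairwise differences per usable site,
  ``k_hat / sites_used`` with ``k_hat = sum_{i<j} d_ij / C(n,2)``;
* Watterson's estimator ``theta_w = S / (a1 * sites_used)``,
  ``a1 = sum_{i=1}^{n-1} 1/i``;
* unbiased haplotype diversity ``h = n (1 - sum p_i^2) / (n - 1)``.

``k_hat`` (per-sequence scale) is retained alongside per-site ``pi`` because
Tajima's D is defined on the per-sequence scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import (
    AlignedSequenceSet,
    PairwiseDifferenceMatrix,
    call_haplotypes,
    pairwise_differences,
    segregating_sites,
)


def harmonic_number(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2) for i = 1..n."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


def nucleotide_diversity(d: PairwiseDifferenceMatrix) -> tuple[float, float]:
    """Return ``(pi, k_hat)`` from a pairwise difference matrix."""
    n = d.n
    if n < 2:
        raise DataError("nucleotide diversity requires n >= 2")
    if d.sites_used < 1:
        raise DataError("nucleotide diversity requires sites_used >= 1")
    total = float(np.triu(d.d, 1).sum())
    k_hat = total / (n * (n - 1) / 2)
    return k_hat / d.sites_used, k_hat


def watterson_theta(S: int, n: int, sites_used: int) -> float:
    """Per-site Watterson estimate ``S / (a1 * sites_used)``."""
    if n < 2:
        raise DataError("Watterson's theta requires n >= 2")
    if S == 0:
        return 0.0
    return S / (harmonic_number(n - 1) * sites_used)


def haplotype_diversity(counts) -> float:
    """Unbiased gene (haplotype) diversity from per-haplotype counts."""
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise DataError("haplotype diversity requires total n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


@dataclass
class DiversitySummary:
    """Diversity of one population at one marker."""

    population: str
    n: int
    S: int
    pi: float
    theta_w: float
    h: float
    k_hat: float


@dataclass
class AcrossPopulationSummary:
    """Equal-weight mean +/- sample SD of a statistic across populations."""

    statistic: str
    mean: float
    sd: float
    min: float
    max: float


def summarize_populations(values, statistic: str = "statistic") -> AcrossPopulationSummary:
    """Arithmetic mean and sample SD (n-1) over populations, equally weighted."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise DataError("across-population summary requires >= 2 populations")
    return AcrossPopulationSummary(
        statistic, float(v.mean()), float(v.std(ddof=1)), float(v.min()), float(v.max())
    )


def population_diversity_table(a: AlignedSequenceSet, gap_policy: str = "complete") -> pd.DataFrame:
    """Per-population diversity report (one row per population).

    Columns: population, n, S, h, pi, theta_w, k_hat.  Statistics for each
    population are computed on that population's sub-alignment, re-applying
    the gap policy within the subset.
    """
    rows = []
    for pop, sub in a.by_population().items():
        if sub.n < 2:
            raise DataError(f"population {pop}: need >= 2 samples")
        S = len(segregating_sites(sub, gap_policy))
        d = pairwise_differences(sub, gap_policy)
        pi, k_hat = nucleotide_diversity(d)
        hap = call_haplotypes(sub, gap_policy)
        h = haplotype_diversity(hap.total_counts()) if hap.n_haplotypes > 1 else 0.0
        rows.append(DiversitySummary(pop, sub.n, S, pi,
                                     watterson_theta(S, sub.n, d.sites_used),
                                     h, k_hat))
    return pd.DataFrame([r.__dict__ for r in rows])
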