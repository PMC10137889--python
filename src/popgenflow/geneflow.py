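"""Pollen-to-seed gene-flow ratio under the island model (Ennos contrast).

Under the classical island model, differentiation at a maternally inherited
(seed-dispersed) marker is ``Fstm = 1/(1 + 2 Ne ms)`` and at a biparental
marker ``Fstn = 1/(1 + 2 Ne (ms + mp/2))``, where ``ms`` and ``mp`` are the
seed and pollen migration rates.  Contrasting the two eliminates ``Ne`` and
yields the Ennos (1994) ratio for haploid-transmitted markers with no
inbreeding:

    mp/ms = [(1 - Fstn)/Fstn] * [Fstm/(1 - Fstm)] - 2

Uncertainty comes from delete-one-population jackknifing of the underlying
differentiation estimates (or from per-locus dispersion when few loci exist)
propagated through the ratio with a first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .errors import DataError


def ennos_ratio(fstn: float, fstm: float) -> float:
    """Point estimate of mp/ms from biparental (fstn) and maternal (fstm) Fst."""
    for name, v in (("fstn", fstn), ("fstm", fstm)):
        if not 0.0 < v < 1.0:
            raise DataError(f"{name} = {v} is outside the open interval (0, 1)")
    return (1.0 - fstn) / fstn * (fstm / (1.0 - fstm)) - 2.0


def jackknife(recompute: Callable[[int], float], units: Sequence) -> tuple[float, float, float]:
    """Delete-one jackknife over ``units`` (typically populations).

    ``recompute(i)`` must return the statistic with unit ``i`` removed.
    Returns ``(mean, variance, sd)`` with the standard jackknife variance
    ``(P-1)/P * sum (theta_i - mean)^2``.
    """
    P = len(units)
    if P < 3:
        raise DataError("jackknife requires >= 3 units")
    thetas = []
    for i, unit in enumerate(units):
        try:
            thetas.append(float(recompute(i)))
        except Exception as exc:  # noqa: BLE001 - annotate which unit failed
            raise DataError(f"jackknife recomputation failed deleting {unit!r}: {exc}") from exc
    mean = sum(thetas) / P
    var = (P - 1) / P * sum((t - mean) ** 2 for t in thetas)
    return mean, var, math.sqrt(var)


def per_locus_sd(estimates: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-locus differentiation estimates."""
    vals = [float(v) for v in estimates]
    if len(vals) < 2:
        raise DataError("per-locus summary requires >= 2 loci")
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return mean, math.sqrt(var)


def ratio_sd(fstn: float, fstm: float, sd_fstn: float, sd_fstm: float) -> float:
    """Delta-method SD of the Ennos ratio, inputs treated as independent.

    dR/dfstn = -fstm / ((1-fstm) fstn^2);  dR/dfstm = (1-fstn) / (fstn (1-fstm)^2)
    """
    ennos_ratio(fstn, fstm)  # domain check
    if sd_fstn < 0 or sd_fstm < 0:
        raise DataError("standard deviations must be non-negative")
    d_n = -fstm / ((1.0 - fstm) * fstn**2)
    d_m = (1.0 - fstn) / (fstn * (1.0 - fstm) ** 2)
    return math.sqrt((d_n * sd_fstn) ** 2 + (d_m * sd_fstm) ** 2)


@dataclass
class GeneFlowResult:
    """Ennos mp/ms estimate with uncertainty and the implied scaled seed flow."""

    fstm: float
    fstn: float
    sd_fstm: float
    sd_fstn: float
    ratio: float
    sd_ratio: float
    nem: float  # implied 2 Ne ms = 1/Fstm - 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def gene_flow_from_fst(fstn: float, fstm: float,
                       sd_fstn: float = 0.0, sd_fstm: float = 0.0) -> GeneFlowResult:
    """Assemble a :class:`GeneFlowResult` from differentiation estimates."""
    ratio = ennos_ratio(fstn, fstm)
    sd = ratio_sd(fstn, fstm, sd_fstn, sd_fstm)
    return GeneFlowResult(fstm, fstn, sd_fstm, sd_fstn, ratio, sd, 1.0 / fstm - 1.0)
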