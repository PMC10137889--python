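"""Coalescent simulators: finite-island model, two-epoch expansion, fixtures.

The island model is the structured coalescent on ``d`` demes of ``N`` haploid
gene copies: within a deme every lineage pair coalesces at rate ``1/N`` per
generation; each lineage migrates at rate ``m`` per generation into the
metapopulation pool and lands in a deme drawn uniformly from all ``d``
(Wright's island-model convention).  With that convention the expected
pairwise-coalescence-time differentiation is exactly ``Fst = 1/(1 + 2Nm)``
for any number of demes, matching the island-model relation the Ennos
gene-flow contrast assumes.

Mutations are Poisson on branches under infinite sites and mapped to
distinct alignment columns; if a genealogy carries more mutations than
columns the replicate is redrawn (logged).

The two-epoch ("sudden expansion") simulator switches the coalescence rate
from ``1/N1`` (present) to ``1/N0`` (ancestral) at ``t`` generations back,
the model behind mismatch-distribution demography (``theta0 = 2 N0 u``,
``theta1 = 2 N1 u``, ``tau = 2 u t`` with ``u`` the per-locus rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import AlignedSequenceSet, PopulationMetadata, write_metadata

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Genealogy machinery
# ---------------------------------------------------------------------------

def _island_genealogy(samples_per_deme: list[int], scaled_migration: float, rng):
    """Structured-coalescent genealogy under the finite island model.

    Time is measured in units of N generations.  ``scaled_migration`` is
    2Nm with m the pool-migration rate, so the effective per-lineage rate of
    actually changing demes is (2Nm/2) * (d-1)/d per scaled unit.

    Returns ``(parent, time)`` arrays over 2n-1 nodes (samples 0..n-1,
    internal nodes in coalescence order; root parent = -1).
    """
    d = len(samples_per_deme)
    n = int(sum(samples_per_deme))
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    demes: list[list[int]] = []
    node = 0
    for c in samples_per_deme:
        demes.append(list(range(node, node + c)))
        node += c
    move_rate = 0.0 if d == 1 else scaled_migration / 2.0 * (d - 1) / d
    t = 0.0
    k = n
    nxt = n
    while k > 1:
        pairs = np.array([len(g) * (len(g) - 1) / 2.0 for g in demes])
        coal = pairs.sum()
        mig = k * move_rate
        total = coal + mig
        t += rng.exponential(1.0 / total)
        if rng.random() * total < coal:
            g = rng.choice(d, p=pairs / coal) if d > 1 else 0
            grp = demes[g]
            i, j = rng.choice(len(grp), size=2, replace=False)
            a, b = grp[i], grp[j]
            for idx in sorted((i, j), reverse=True):
                grp.pop(idx)
            parent[a] = parent[b] = nxt
            time[nxt] = t
            grp.append(nxt)
            nxt += 1
            k -= 1
        else:
            sizes = np.array([len(g) for g in demes], dtype=float)
            g = rng.choice(d, p=sizes / k)
            grp = demes[g]
            lin = grp.pop(rng.integers(len(grp)))
            dest = rng.integers(d - 1)
            if dest >= g:
                dest += 1
            demes[dest].append(lin)
    return parent, time


def _two_epoch_genealogy(n: int, n0: float, n1: float, t_exp: float, rng):
    """Single-population genealogy with pair hazard 1/n1 until t_exp, then 1/n0.

    Time units are whatever units n0, n1 and t_exp share (generations, or
    mutational units when the caller passes theta0/theta1/tau with mutation
    rate 1/2 per lineage).
    """
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        size = n1 if t < t_exp else n0
        rate = k * (k - 1) / 2.0 / size
        dt = rng.exponential(1.0 / rate)
        if t < t_exp and t + dt > t_exp:
            t = t_exp  # memoryless: re-draw under the ancestral rate
            continue
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active.append(nxt)
        nxt += 1
    return parent, time


def _descendants(parent: np.ndarray, n: int) -> np.ndarray:
    """Boolean (nodes x samples) descendant-sample matrix.

    Internal nodes are created after their children, so a single index-order
    sweep suffices.
    """
    m = parent.size
    desc = np.zeros((m, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    for i in range(m - 1):
        if parent[i] >= 0:
            desc[parent[i]] |= desc[i]
    return desc


def _branch_mutations(parent: np.ndarray, time: np.ndarray, rate: float, rng) -> np.ndarray:
    """Poisson mutation counts per node's parent branch (root gets 0)."""
    lengths = np.where(parent >= 0, time[np.clip(parent, 0, None)] - time, 0.0)
    return rng.poisson(rate * lengths)


def _pairwise_from_mutations(parent, time, n, rate, rng) -> np.ndarray:
    """Pairwise difference counts implied by Poisson mutations on branches."""
    counts = _branch_mutations(parent, time, rate, rng)
    desc = _descendants(parent, n)
    w = counts.astype(float)
    X = desc.astype(float)
    s = w @ X
    M = (X * w[:, None]).T @ X
    D = s[:, None] + s[None, :] - 2.0 * M
    np.fill_diagonal(D, 0.0)
    return np.rint(D).astype(np.int64)


class _MutationOverflow(Exception):
    """More mutations than alignment columns; the replicate must be redrawn."""


def _sequences(parent, time, n, L, rate, rng, max_tries: int = 5) -> np.ndarray:
    """Infinite-sites mutations mapped to distinct columns of an L-column alignment."""
    for attempt in range(max_tries):
        counts = _branch_mutations(parent, time, rate, rng)
        total = int(counts.sum())
        if total <= L:
            break
        logger.info("mutation count %d exceeds L=%d; redrawing (attempt %d)",
                    total, L, attempt + 1)
    else:
        raise _MutationOverflow
    desc = _descendants(parent, n)
    ref = rng.choice(_BASES, size=L)
    mat = np.tile(ref, (n, 1))
    cols = rng.choice(L, size=total, replace=False)
    ci = 0
    for node in np.flatnonzero(counts):
        for _ in range(counts[node]):
            col = cols[ci]
            ci += 1
            alt = _BASES[_BASES != ref[col]][rng.integers(3)]
            mat[desc[node, :], col] = alt
    return mat


# ---------------------------------------------------------------------------
# Public configs and simulators
# ---------------------------------------------------------------------------

@dataclass
class IslandModelConfig:
    """Finite island model: d demes of N haploid copies, pool migration m."""

    n_demes: int
    deme_size: int
    migration: float  # per lineage per generation, into the island pool
    samples_per_deme: int | list[int]
    mu: float  # per site per generation
    sites: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_demes < 1 or self.deme_size < 1 or self.sites < 1:
            raise ConfigError("n_demes, deme_size and sites must be positive")
        if not 0.0 <= self.migration <= 1.0:
            raise ConfigError("migration must lie in [0, 1]")
        if self.n_demes > 1 and self.migration == 0.0:
            raise ConfigError("migration must be > 0 with multiple demes: with m = 0 "
                              "demes never share ancestry and the genealogy has no "
                              "common root (approach the limit with a small m)")
        if self.mu < 0:
            raise ConfigError("mutation rate must be non-negative")

    @property
    def sample_sizes(self) -> list[int]:
        if isinstance(self.samples_per_deme, int):
            return [self.samples_per_deme] * self.n_demes
        if len(self.samples_per_deme) != self.n_demes:
            raise ConfigError("samples_per_deme list must have n_demes entries")
        return list(self.samples_per_deme)

    @property
    def scaled_migration(self) -> float:
        """2Nm, the quantity Fst = 1/(1 + 2Nm) is written in."""
        return 2.0 * self.deme_size * self.migration


def _deme_labels(sizes: list[int], codes: list[str] | None):
    if codes is None:
        codes = [f"P{i + 1:02d}" for i in range(len(sizes))]
    ids, popmap = [], {}
    for code, c in zip(codes, sizes):
        for j in range(c):
            s = f"{code}_{j + 1:03d}"
            ids.append(s)
            popmap[s] = code
    return ids, popmap


def simulate_island(cfg: IslandModelConfig, pop_codes: list[str] | None = None,
                    rng=None, marker_name: str = "sim") -> AlignedSequenceSet:
    """Simulate one marker's alignment under the finite island model."""
    sizes = cfg.sample_sizes
    if max(sizes) > 10 * cfg.deme_size:
        logger.warning("sample size exceeds 10x deme size; coalescent approximation strained")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    # time is in units of N generations -> per-branch mutation rate N*mu*L
    rate = cfg.deme_size * cfg.mu * cfg.sites
    for attempt in range(30):
        parent, time = _island_genealogy(sizes, cfg.scaled_migration, rng)
        try:
            mat = _sequences(parent, time, sum(sizes), cfg.sites, rate, rng)
            break
        except _MutationOverflow:
            logger.info("genealogy too long for L=%d; redrawing genealogy "
                        "(attempt %d)", cfg.sites, attempt + 1)
    else:
        raise ConfigError(f"mutations persistently exceed alignment length "
                          f"L={cfg.sites}; reduce mu or increase sites")
    ids, popmap = _deme_labels(sizes, pop_codes)
    return AlignedSequenceSet(ids, popmap, mat, marker_name)


def simulate_two_systems(cfg_base: IslandModelConfig, ms: float, mp: float,
                         pop_codes: list[str] | None = None):
    """Maternal (seed-only) and biparental (seed + pollen) marker pair.

    The maternal system migrates at ``ms`` per generation, the biparental one
    at ``ms + mp/2`` (a pollen grain moves only half a biparental genome's
    ancestry per event under haploid bookkeeping).  Genealogies are
    independent; deme structure and sample labels are shared.
    """
    if ms < 0 or mp < 0 or ms + mp / 2.0 > 1.0:
        raise ConfigError("need ms, mp >= 0 and ms + mp/2 <= 1")
    rng = np.random.default_rng(cfg_base.seed)
    base = cfg_base.__dict__ | {}
    maternal_cfg = IslandModelConfig(**{**base, "migration": ms})
    biparental_cfg = IslandModelConfig(**{**base, "migration": ms + mp / 2.0})
    maternal = simulate_island(maternal_cfg, pop_codes, rng=rng, marker_name="maternal")
    biparental = simulate_island(biparental_cfg, pop_codes, rng=rng, marker_name="biparental")
    return maternal, biparental


@dataclass
class ExpansionConfig:
    """Two-epoch model: size N0 until t generations ago, N1 afterwards."""

    n0: float
    n1: float
    t: float
    mu: float
    sites: int
    n: int
    seed: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1) <= 0 or self.t < 0 or self.n < 2 or self.sites < 1:
            raise ConfigError("invalid expansion configuration")

    @property
    def tau(self) -> float:
        """Implied mutational time since expansion, tau = 2 u t (locus-wide u)."""
        return 2.0 * self.mu * self.sites * self.t


def simulate_expansion(cfg: ExpansionConfig, rng=None,
                       marker_name: str = "expansion") -> AlignedSequenceSet:
    """Simulate one panmictic sample under the sudden-expansion model."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    for attempt in range(30):
        parent, time = _two_epoch_genealogy(cfg.n, cfg.n0, cfg.n1, cfg.t, rng)
        try:
            mat = _sequences(parent, time, cfg.n, cfg.sites, cfg.mu * cfg.sites, rng)
            break
        except _MutationOverflow:
            logger.info("genealogy too long for L=%d; redrawing (attempt %d)",
                        cfg.sites, attempt + 1)
    else:
        raise ConfigError(f"mutations persistently exceed alignment length "
                          f"L={cfg.sites}; reduce mu or increase sites")
    ids, popmap = _deme_labels([cfg.n], ["P01"])
    return AlignedSequenceSet(ids, popmap, mat, marker_name)


def two_epoch_pairwise_matrix(n: int, theta0: float, theta1: float, tau: float,
                              rng) -> np.ndarray:
    """Pairwise difference matrix drawn from the two-epoch coalescent.

    Parameterized directly in mismatch units (theta0, theta1, tau): time is
    measured in expected pairwise mutations, so the per-lineage mutation
    rate is 1/2 and pair coalescence hazards are 1/theta1 then 1/theta0.
    Infinite sites (no alignment-length cap); used for parametric bootstraps
    and as a simulation oracle for the closed-form mismatch spectrum.
    """
    t0 = max(theta0, 1e-9)
    t1 = max(theta1, 1e-9)
    parent, time = _two_epoch_genealogy(n, t0, t1, tau, rng)
    return _pairwise_from_mutations(parent, time, n, 0.5, rng)


# ---------------------------------------------------------------------------
# Study-like fixture
# ---------------------------------------------------------------------------

#: Ten-population metadata table (code, lon E, lat N, elevation m, AAP mm, AAT C).
STUDY_METADATA = [
    PopulationMetadata("LZ", 106.86, 22.35, 269, 1260.0, 22.2),
    PopulationMetadata("FS", 108.35, 21.70, 235, 2512.0, 21.8),
    PopulationMetadata("NN", 108.37, 22.82, 80, 1304.2, 21.7),
    PopulationMetadata("GZ", 113.27, 23.13, 10, 1696.5, 22.1),
    PopulationMetadata("YF", 112.05, 22.92, 346, 1670.5, 21.5),
    PopulationMetadata("BS", 99.17, 25.14, 1670, 1710.0, 17.4),
    PopulationMetadata("DH", 98.61, 24.44, 780, 1544.0, 18.9),
    PopulationMetadata("JH", 100.81, 22.03, 552, 1197.0, 21.0),
    PopulationMetadata("MS", 98.59, 24.43, 913, 1650.0, 19.6),
    PopulationMetadata("ML", 101.57, 21.46, 631, 1540.0, 21.0),
]

#: Biparental-marker sample sizes per population (total 239).
ITS_SAMPLE_SIZES = [22, 19, 22, 26, 15, 33, 29, 32, 23, 18]

#: Maternal-marker sample sizes per population (total 161).
MT_SAMPLE_SIZES = [15, 13, 16, 18, 10, 22, 19, 21, 15, 12]

# (pop index, counts per haplotype H1..H4); six populations fixed, four with
# two haplotypes at frequencies giving unbiased h between 0.42 and 0.52.
_MT_HAPLOTYPE_COUNTS = [
    (0, [15, 0, 0, 0]),   # LZ fixed H1
    (1, [0, 13, 0, 0]),   # FS fixed H2
    (2, [11, 0, 0, 5]),   # NN: h = 0.458
    (3, [18, 0, 0, 0]),   # GZ fixed H1
    (4, [0, 0, 10, 0]),   # YF fixed H3
    (5, [0, 22, 0, 0]),   # BS fixed H2
    (6, [7, 0, 0, 12]),   # DH: h = 0.491
    (7, [0, 0, 21, 0]),   # JH fixed H3
    (8, [0, 10, 0, 5]),   # MS: h = 0.476
    (9, [0, 0, 8, 4]),    # ML: h = 0.485
]

#: Segregating positions (1-based) and haplotype states of the maternal marker.
MT_POSITIONS = (318, 647)
MT_HAPLOTYPE_STATES = {"H1": "AA", "H2": "CA", "H3": "AC", "H4": "CC"}


@dataclass
class FixtureBundle:
    """In-memory study-like data plus (optionally) the files written for it."""

    mtdna: AlignedSequenceSet
    its: AlignedSequenceSet
    metadata: list[PopulationMetadata]
    paths: dict[str, Path] = field(default_factory=dict)


def make_paper_fixture(seed: int, outdir: str | Path | None = None) -> FixtureBundle:
    """Build the study-like synthetic dataset.

    The maternal (mtDNA-like) alignment is a 1050 bp concatenated-amplicon
    analogue: 161 samples over 10 populations, exactly two biallelic
    segregating sites (positions 318 and 647) defining four haplotypes, six
    populations fixed and four polymorphic with h ~ 0.42-0.52.  The
    biparental (ITS-like) alignment is an island-model simulation of 239
    samples (619 bp) calibrated to high within-population diversity
    (pi ~ 0.12) and weak differentiation (phi_st ~ 0.03, i.e. 2Nm = 33).
    """
    rng = np.random.default_rng(seed)
    codes = [m.code for m in STUDY_METADATA]

    # maternal marker: constant background plus the two diagnostic columns
    L_mt = 1050
    background = rng.choice(_BASES, size=L_mt)
    hap_names = list(MT_HAPLOTYPE_STATES)
    ids: list[str] = []
    popmap: dict[str, str] = {}
    rows = []
    for pop_idx, hap_counts in _MT_HAPLOTYPE_COUNTS:
        code = codes[pop_idx]
        j = 0
        for hap, count in zip(hap_names, hap_counts):
            states = MT_HAPLOTYPE_STATES[hap]
            for _ in range(count):
                j += 1
                s = f"{code}_{j:03d}"
                row = background.copy()
                for pos, state in zip(MT_POSITIONS, states):
                    row[pos - 1] = ord(state)
                ids.append(s)
                popmap[s] = code
                rows.append(row)
    mtdna = AlignedSequenceSet(ids, popmap, np.vstack(rows), "mtDNA")

    # biparental marker: island-model coalescent in the weak-structure regime
    deme_size = 1000
    its_cfg = IslandModelConfig(
        n_demes=10,
        deme_size=deme_size,
        migration=33.0 / (2 * deme_size),       # 2Nm = 33 -> Fst ~ 0.029
        samples_per_deme=ITS_SAMPLE_SIZES,
        mu=0.1185 / (2 * deme_size * 10),       # within-pop pi ~ 2 N d mu = 0.1185
        sites=619,
        seed=int(rng.integers(2**31 - 1)),
    )
    its = simulate_island(its_cfg, pop_codes=codes, marker_name="ITS")

    bundle = FixtureBundle(mtdna, its, list(STUDY_METADATA))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mtdna_fasta": outdir / "mtdna.fasta",
            "its_fasta": outdir / "its.fasta",
            "popmap": outdir / "popmap.tsv",
            "metadata": outdir / "metadata.tsv",
        }
        mtdna.write_fasta(paths["mtdna_fasta"])
        its.write_fasta(paths["its_fasta"])
        merged = dict(its.population_of)
        merged.update(mtdna.population_of)
        from .io import write_popmap
        write_popmap(merged, paths["popmap"])
        write_metadata(bundle.metadata, paths["metadata"])
        bundle.paths = paths
    return bundle
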