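"""Alignment data model and standard-format I/O.

Sequences are haploid aligned markers (e.g. nrDNA ITS, concatenated mtDNA
amplicons) read from multi-FASTA, with a two-column popmap assigning each
sample to a population.  All downstream statistics consume the containers
defined here: :class:`AlignedSequenceSet`, :class:`HaplotypeTable`,
:class:`PairwiseDifferenceMatrix` and :class:`PopulationMetadata`.

Missing-data policy
-------------------
The default gap/ambiguity policy is *complete deletion*: any alignment column
containing ``-`` or ``N`` in any sample is dropped before computing
segregating sites, pairwise differences or per-site diversity.  The number of
surviving columns is reported as ``sites_used`` so per-site quantities remain
well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DataError, MappingError

logger = logging.getLogger(__name__)

#: Allowed single-character states, as uint8 ASCII codes.
_ALPHABET = np.frombuffer(b"ACGTN-", dtype=np.uint8)
_NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP_POLICIES = ("complete", "none")


def _encode(seq: str) -> np.ndarray:
    """Uppercase a sequence string and encode it as uint8 codes.

    Characters outside {A,C,G,T,N,-} are mapped to N (counted by caller).
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, _ALPHABET)
    arr[bad] = ord("N")
    return arr, int(bad.sum())


def _decode(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


@dataclass
class AlignedSequenceSet:
    """Aligned haploid sequences with per-sample population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per alignment row.
    population_of
        Mapping sample id -> population code; must cover every sample.
    matrix
        ``(n, L)`` uint8 array of ASCII codes over ``{A,C,G,T,N,-}``.
    marker_name
        Free-text marker label (e.g. ``"ITS"`` or ``"mtDNA"``).
    """

    sample_ids: list[str]
    population_of: dict[str, str]
    matrix: np.ndarray
    marker_name: str = "marker"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must be a non-empty n x L matrix")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError("one sample id per alignment row required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MappingError("sample ids must be unique")
        missing = [s for s in self.sample_ids if s not in self.population_of]
        if missing:
            raise MappingError(f"samples missing from popmap: {missing[:5]}")
        if not np.isin(self.matrix, _ALPHABET).all():
            raise AlignmentError("alignment contains characters outside A,C,G,T,N,-")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def pop_labels(self) -> np.ndarray:
        return np.array([self.population_of[s] for s in self.sample_ids])

    def populations(self) -> list[str]:
        """Population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def sequence(self, i: int) -> str:
        return _decode(self.matrix[i])

    def subset(self, indices) -> "AlignedSequenceSet":
        ids = [self.sample_ids[i] for i in indices]
        return AlignedSequenceSet(
            ids,
            {s: self.population_of[s] for s in ids},
            self.matrix[np.asarray(indices, dtype=int)],
            self.marker_name,
        )

    def by_population(self) -> dict[str, "AlignedSequenceSet"]:
        labels = self.pop_labels
        return {
            p: self.subset(np.flatnonzero(labels == p)) for p in self.populations()
        }

    # -- I/O ---------------------------------------------------------------
    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.sequence(i)), id=s, description="")
            for i, s in enumerate(self.sample_ids)
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_popmap(self, path) -> None:
        write_popmap({s: self.population_of[s] for s in self.sample_ids}, path)


def read_popmap(path) -> dict[str, str]:
    """Read a two-column tab-separated sample->population map.

    Lines starting with ``#`` and blank lines are ignored.
    """
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MappingError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, pop = parts
            if sample in popmap:
                raise MappingError(f"{path}:{lineno}: duplicate sample {sample!r}")
            popmap[sample] = pop
    if not popmap:
        raise MappingError(f"{path}: empty popmap")
    return popmap


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_alignment(fasta_path, popmap, marker_name: str | None = None) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA plus popmap into an :class:`AlignedSequenceSet`.

    ``popmap`` may be a path or an already-parsed dict.  Lower-case bases are
    upper-cased; characters outside the alphabet are mapped to ``N`` with a
    logged warning count.
    """
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_bad = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if len(rec.seq) == 0:
            raise AlignmentError(f"empty FASTA record {rec.id!r}")
        row, bad = _encode(str(rec.seq))
        n_bad += bad
        ids.append(rec.id)
        rows.append(row)
    if not rows:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"{fasta_path}: unequal record lengths {sorted(lengths)}")
    missing = [s for s in ids if s not in popmap]
    if missing:
        raise MappingError(f"samples absent from popmap: {missing[:5]}")
    if n_bad:
        logger.warning("%s: %d characters outside A,C,G,T,N,- mapped to N", fasta_path, n_bad)
    name = marker_name if marker_name is not None else "marker"
    return AlignedSequenceSet(ids, {s: popmap[s] for s in ids}, np.vstack(rows), name)


def concatenate_loci(a: AlignedSequenceSet, b: AlignedSequenceSet,
                     marker_name: str | None = None) -> AlignedSequenceSet:
    """Concatenate two locus alignments sample-wise (e.g. F1-R1 + F2-R2).

    Samples present in only one input are dropped (logged); the retained
    order follows the first argument.
    """
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared:
        raise MappingError("no samples shared between the two loci")
    dropped = (set(a.sample_ids) | set(b.sample_ids)) - set(shared)
    if dropped:
        logger.info("concatenate_loci: dropping %d samples absent from one locus", len(dropped))
    ia = {s: i for i, s in enumerate(a.sample_ids)}
    ib = {s: i for i, s in enumerate(b.sample_ids)}
    mat = np.hstack([
        a.matrix[[ia[s] for s in shared]],
        b.matrix[[ib[s] for s in shared]],
    ])
    name = marker_name if marker_name is not None else f"{a.marker_name}+{b.marker_name}"
    return AlignedSequenceSet(shared, {s: a.population_of[s] for s in shared}, mat, name)


# ---------------------------------------------------------------------------
# Site filtering, segregating sites, haplotypes, pairwise differences
# ---------------------------------------------------------------------------

def usable_columns(a: AlignedSequenceSet, gap_policy: str = "complete") -> np.ndarray:
    """Boolean mask of alignment columns surviving the gap policy.

    ``complete``: a column is unusable if any sample carries ``-`` or ``N``.
    ``none``: every column is kept (missing states simply never match).
    """
    if gap_policy not in _GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if gap_policy == "none":
        return np.ones(a.length, dtype=bool)
    return np.isin(a.matrix, _NUCLEOTIDES).all(axis=0)


def segregating_sites(a: AlignedSequenceSet, gap_policy: str = "complete") -> list[int]:
    """1-based positions of columns with >= 2 distinct nucleotide states."""
    if a.n < 2:
        raise DataError("segregating sites require n >= 2 sequences")
    keep = usable_columns(a, gap_policy)
    positions = []
    for j in np.flatnonzero(keep):
        col = a.matrix[:, j]
        states = np.unique(col[np.isin(col, _NUCLEOTIDES)])
        if states.size >= 2:
            positions.append(int(j) + 1)
    return positions


@dataclass
class HaplotypeTable:
    """Distinct haplotypes over segregating sites with per-population counts.

    ``counts`` is a (haplotype x population) DataFrame; haplotypes are named
    H1, H2, ... in descending total frequency (ties broken lexicographically
    by state-vector), so "H1 is the most frequent haplotype" is reproducible.
    """

    site_positions: list[int]
    haplotypes: list[str]
    counts: pd.DataFrame
    total_n: int

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("haplotype counts must be non-negative")
        if int(self.counts.to_numpy().sum()) != self.total_n:
            raise DataError("total_n must equal the sum of counts")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def distance_matrix(self) -> np.ndarray:
        """Hamming distances between haplotype state-vectors."""
        arr = np.array([list(h) for h in self.haplotypes])
        return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)


def call_haplotypes(a: AlignedSequenceSet, gap_policy: str = "complete") -> HaplotypeTable:
    """Collapse samples by their state-vector over segregating sites.

    Samples carrying ``N`` or ``-`` at any segregating site are excluded from
    the counts (logged); under the default complete-deletion policy such
    samples cannot occur because the offending columns are already removed.
    """
    positions = segregating_sites(a, gap_policy) if a.n >= 2 else []
    cols = [p - 1 for p in positions]
    pops = a.populations()
    if not cols:
        counts = pd.DataFrame(
            {p: [int((a.pop_labels == p).sum())] for p in pops}, index=["H1"]
        )
        return HaplotypeTable([], [""], counts, a.n)
    sub = a.matrix[:, cols]
    ok = np.isin(sub, _NUCLEOTIDES).all(axis=1)
    if not ok.all():
        logger.info("call_haplotypes: excluding %d samples with missing states", int((~ok).sum()))
    labels = a.pop_labels
    hapstrings = ["".join(chr(c) for c in row) for row in sub]
    tally: dict[str, dict[str, int]] = {}
    for keep, hap, pop in zip(ok, hapstrings, labels):
        if keep:
            tally.setdefault(hap, {})
            tally[hap][pop] = tally[hap].get(pop, 0) + 1
    totals = {h: sum(d.values()) for h, d in tally.items()}
    ordered = sorted(tally, key=lambda h: (-totals[h], h))
    counts = pd.DataFrame(
        [[tally[h].get(p, 0) for p in pops] for h in ordered],
        index=[f"H{i + 1}" for i in range(len(ordered))],
        columns=pops,
    )
    return HaplotypeTable(positions, ordered, counts, int(ok.sum()))


@dataclass
class PairwiseDifferenceMatrix:
    """Symmetric matrix of per-pair nucleotide difference counts."""

    labels: list[str]
    d: np.ndarray
    sites_used: int
    populations: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        if self.d.shape[0] != self.d.shape[1]:
            raise DataError("difference matrix must be square")
        if not np.array_equal(self.d, self.d.T) or np.diag(self.d).any():
            raise DataError("difference matrix must be symmetric with zero diagonal")
        if (self.d < 0).any() or (self.d > self.sites_used).any():
            raise DataError("difference counts must lie in [0, sites_used]")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def pairwise_differences(a: AlignedSequenceSet, gap_policy: str = "complete") -> PairwiseDifferenceMatrix:
    """Count per-pair differing columns among those surviving the gap policy."""
    if a.n < 2:
        raise DataError("pairwise differences require n >= 2 sequences")
    keep = usable_columns(a, gap_policy)
    sites_used = int(keep.sum())
    if sites_used == 0:
        raise DataError("no usable columns after gap filtering")
    sub = a.matrix[:, keep]
    # broadcasting is fine at the package's scale (hundreds of samples)
    d = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).astype(np.int64)
    return PairwiseDifferenceMatrix(list(a.sample_ids), d, sites_used, a.pop_labels)


# ---------------------------------------------------------------------------
# Population metadata (Table-1-style)
# ---------------------------------------------------------------------------

#: Canonical column names for the metadata table.
METADATA_COLUMNS = ["code", "longitude", "latitude", "elevation", "aap", "aat"]


@dataclass(frozen=True)
class PopulationMetadata:
    """One sampled population: location and climate covariates.

    ``aap`` is annual average precipitation (mm/yr), ``aat`` annual average
    temperature (degrees C); longitude/latitude in decimal degrees.
    """

    code: str
    longitude: float
    latitude: float
    elevation: float
    aap: float
    aat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise DataError(f"{self.code}: longitude {self.longitude} out of [-180, 180]")
        if not -90.0 <= self.latitude <= 90.0:
            raise DataError(f"{self.code}: latitude {self.latitude} out of [-90, 90]")


def read_metadata(path) -> list[PopulationMetadata]:
    """Read a tab-separated metadata table with the canonical header."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"metadata missing columns: {sorted(missing)}")
    rows = [PopulationMetadata(
        str(r.code), float(r.longitude), float(r.latitude),
        float(r.elevation), float(r.aap), float(r.aat))
        for r in df.itertuples()]
    codes = [m.code for m in rows]
    if len(set(codes)) != len(codes):
        raise DataError("metadata population codes must be unique")
    return rows


def write_metadata(meta: list[PopulationMetadata], path) -> None:
    pd.DataFrame([m.__dict__ for m in meta])[METADATA_COLUMNS].to_csv(
        path, sep="\t", index=False)
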