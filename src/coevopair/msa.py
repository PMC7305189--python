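"""Alignment I/O, identity filtering, sequence reweighting and the Cys tail census.

Conventions
-----------
* Column indices are 0-based half-open internally; reports use 1-based
  numbering to match reference-sequence residue numbering.
* Sequence identity between two aligned rows is the number of columns where
  both carry the same non-gap, non-'X' character, divided by the number of
  columns where at least one row is non-gap.  'X' always counts as a
  mismatch.  When the denominator is zero the identity is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from . import AA20, ALPHABET, GAP, Q, UNKNOWN

log = logging.getLogger(__name__)

_VALID = set(AA20) | {GAP, UNKNOWN}
_CHAR_TO_STATE = {c: i for i, c in enumerate(ALPHABET)}
# 'X' is encoded as the gap state for model fitting but tracked separately
_CHAR_TO_STATE[UNKNOWN] = Q - 1

__all__ = [
    "SequenceRecord",
    "Alignment",
    "WeightingResult",
    "CysCensus",
    "read_alignment",
    "write_alignment",
    "pairwise_identity",
    "identity_matrix",
    "filter_redundant",
    "filter_gappy_columns",
    "sequence_weights",
    "compute_nf",
    "map_reference_column",
    "cys_tail_census",
    "write_census_tsv",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned row: an identifier, aligned residues, optional provenance."""

    id: str
    residues: str
    source: str | None = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered set of equal-length aligned rows with optional weights."""

    records: list[SequenceRecord]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        ncols = len(self.records[0].residues)
        if ncols == 0:
            raise ValueError("alignment rows must be non-empty")
        for rec in self.records:
            if len(rec.residues) != ncols:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {ncols}"
                )
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.records),):
                raise ValueError("weights must have one entry per record")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise ValueError("weights must lie in (0, 1]")

    @property
    def nrows(self) -> int:
        return len(self.records)

    @property
    def ncols(self) -> int:
        return len(self.records[0].residues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records

    def __iter__(self):
        return iter(self.records)

    def to_states(self) -> np.ndarray:
        """Encode as an (nrows, ncols) int8 state matrix over the 21-letter alphabet."""
        out = np.empty((self.nrows, self.ncols), dtype=np.int8)
        for s, rec in enumerate(self.records):
            out[s] = [_CHAR_TO_STATE[c] for c in rec.residues]
        return out

    def char_matrix(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])

    def subset_rows(self, idx: Sequence[int]) -> "Alignment":
        w = self.weights[list(idx)] if self.weights is not None else None
        return Alignment([self.records[i] for i in idx], weights=w)

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = list(cols)
        recs = [
            replace(r, residues="".join(r.residues[c] for c in cols))
            for r in self.records
        ]
        return Alignment(recs, weights=self.weights)


@dataclass(frozen=True)
class WeightingResult:
    """Per-record weights from identity-neighbour down-weighting."""

    weights: np.ndarray
    neff: float
    id_threshold: float


@dataclass(frozen=True)
class CysCensus:
    n_total: int
    n_ge1: int
    n_ge2: int
    per_record: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (self.n_ge2 <= self.n_ge1 <= self.n_total):
            raise ValueError("census counts must satisfy n_ge2 <= n_ge1 <= n_total")


def _sanitize(seq: str, rec_id: str, counter: list[int]) -> str:
    up = seq.upper().replace(".", GAP)
    bad = sum(1 for c in up if c not in _VALID)
    if bad:
        counter[0] += bad
        up = "".join(c if c in _VALID else UNKNOWN for c in up)
    return up


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from FASTA, A3M, or Stockholm.

    A3M lowercase insert states are dropped so every row covers the same
    fixed column set.  Characters outside the 20-aa + gap + 'X' alphabet
    are mapped to 'X' with a logged count.
    """
    path = Path(path)
    if format not in {"fasta", "a3m", "stockholm"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    mapped = [0]
    records: list[SequenceRecord] = []
    if format == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise ValueError(f"cannot parse {path} as stockholm: {exc}") from exc
        for rec in aln:
            records.append(
                SequenceRecord(rec.id, _sanitize(str(rec.seq), rec.id, mapped))
            )
    else:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = str(rec.seq)
            if format == "a3m":
                seq = "".join(c for c in seq if not c.islower())
            records.append(SequenceRecord(rec.id, _sanitize(seq, rec.id, mapped)))
        if not records:
            raise ValueError(f"no sequences parsed from {path} (line 1)")
    if mapped[0]:
        log.warning("%s: mapped %d non-standard characters to 'X'", path, mapped[0])
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: ragged alignment after normalization (lengths {sorted(lengths)})"
        )
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in aln.records]
    if format in {"fasta", "a3m"}:
        SeqIO.write(bio, str(path), "fasta")
    elif format == "stockholm":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(bio), str(path), "stockholm")
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of shared-occupancy columns with identical non-gap, non-X residues."""
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"length mismatch: {a.id!r} ({len(a)}) vs {b.id!r} ({len(b)})"
        )
    match = 0
    union = 0
    for ca, cb in zip(a.residues, b.residues):
        ga, gb = ca == GAP, cb == GAP
        if ga and gb:
            continue
        union += 1
        if ca == cb and not ga and ca != UNKNOWN:
            match += 1
    return match / union if union else 0.0


def _encode_for_identity(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """One-hot over match-eligible characters plus gap indicator, for BLAS identity."""
    chars = aln.char_matrix()
    gap = (chars == GAP).astype(np.float32)
    onehot = np.zeros((aln.nrows, aln.ncols, len(AA20)), dtype=np.float32)
    for k, c in enumerate(AA20):
        onehot[:, :, k] = chars == c
    return onehot.reshape(aln.nrows, -1), gap


def identity_matrix(aln: Alignment) -> np.ndarray:
    """All-pairs identity under the module's identity convention (vectorized)."""
    onehot, gap = _encode_for_identity(aln)
    matches = onehot @ onehot.T
    both_gap = gap @ gap.T
    union = aln.ncols - both_gap
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(union > 0, matches / union, 0.0)
    np.fill_diagonal(ident, 1.0)
    return ident.astype(float)


def filter_redundant(aln: Alignment, max_id: float = 0.90) -> Alignment:
    """Greedy order-preserving redundancy filter.

    A record is kept iff its identity to every previously kept record
    is <= ``max_id``.  First-seen wins.
    """
    if not (0 < max_id <= 1):
        raise ValueError(f"max_id must lie in (0, 1], got {max_id}")
    onehot, gap = _encode_for_identity(aln)
    kept: list[int] = []
    kept_oh: list[np.ndarray] = []
    kept_gap: list[np.ndarray] = []
    for s in range(aln.nrows):
        if kept:
            oh = np.asarray(kept_oh)
            gp = np.asarray(kept_gap)
            matches = oh @ onehot[s]
            union = aln.ncols - gp @ gap[s]
            with np.errstate(divide="ignore", invalid="ignore"):
                ident = np.where(union > 0, matches / union, 0.0)
            if np.any(ident > max_id):
                continue
        kept.append(s)
        kept_oh.append(onehot[s])
        kept_gap.append(gap[s])
    return Alignment([aln.records[i] for i in kept])


def filter_gappy_columns(
    aln: Alignment, max_gap_frac: float = 0.50
) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    Returns the filtered alignment and the list of retained original
    column indices (new index -> original index).
    """
    if not (0 <= max_gap_frac <= 1):
        raise ValueError(f"max_gap_frac must lie in [0, 1], got {max_gap_frac}")
    chars = aln.char_matrix()
    gap_frac = (chars == GAP).mean(axis=0)
    kept = [c for c in range(aln.ncols) if gap_frac[c] <= max_gap_frac]
    if not kept:
        raise ValueError("gap filtering removed every column")
    if len(kept) == aln.ncols:
        return aln, kept
    return aln.subset_columns(kept), kept


def sequence_weights(aln: Alignment, id_threshold: float = 0.80) -> WeightingResult:
    """Down-weight each record by its count of identity neighbours.

    weight_s = 1 / |{t : identity(s, t) >= id_threshold}| (self included);
    neff is the weight sum and always lies in [1, N].
    """
    if not (0 < id_threshold <= 1):
        raise ValueError(f"id_threshold must lie in (0, 1], got {id_threshold}")
    ident = identity_matrix(aln)
    counts = (ident >= id_threshold).sum(axis=1)
    weights = 1.0 / counts
    return WeightingResult(
        weights=weights, neff=float(weights.sum()), id_threshold=id_threshold
    )


def compute_nf(neff: float, ncols: int) -> float:
    """Effective sequence count scaled by sqrt of alignment length."""
    if neff <= 0:
        raise ValueError(f"neff must be positive, got {neff}")
    if ncols <= 0:
        raise ValueError(f"ncols must be positive, got {ncols}")
    return neff / np.sqrt(ncols)


def map_reference_column(aln: Alignment, ref_id: str, ref_resnum: int) -> int:
    """Locate the 0-based column holding 1-based residue ``ref_resnum`` of ``ref_id``.

    The reference row's gap pattern defines the mapping: the k-th non-gap
    character sits at residue number k (1-based).
    """
    for rec in aln.records:
        if rec.id == ref_id:
            n = 0
            for col, c in enumerate(rec.residues):
                if c != GAP:
                    n += 1
                    if n == ref_resnum:
                        return col
            raise ValueError(
                f"reference {ref_id!r} has only {n} residues; "
                f"residue {ref_resnum} not reachable"
            )
    raise KeyError(f"reference sequence {ref_id!r} not found in alignment")


def cys_tail_census(aln: Alignment, anchor_col: int) -> CysCensus:
    """Count records with >=1 / >=2 Cys strictly downstream of ``anchor_col``.

    Gaps are ignored; 'X' is never counted as Cys.  Records gapped at the
    anchor column are still counted using the same column.
    """
    if not (0 <= anchor_col < aln.ncols):
        raise ValueError(
            f"anchor column {anchor_col} out of range [0, {aln.ncols})"
        )
    per = tuple(r.residues[anchor_col + 1 :].count("C") for r in aln.records)
    n_ge1 = sum(1 for c in per if c >= 1)
    n_ge2 = sum(1 for c in per if c >= 2)
    return CysCensus(n_total=aln.nrows, n_ge1=n_ge1, n_ge2=n_ge2, per_record=per)


def write_census_tsv(aln: Alignment, census: CysCensus, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tdownstream_cys\n")
        for rec, n in zip(aln.records, census.per_record):
            fh.write(f"{rec.id}\t{n}\n")
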