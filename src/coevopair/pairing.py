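"""Contig-based pairing of two gene families and paired-alignment construction.

Gene hits arrive as annotations (a GFF3 subset or a 6-column TSV); no gene
calling or database searching happens here.  Pairing modes:

``same_contig``
    pair the single A hit with the single B hit on each contig;
``adjacent_downstream``
    additionally require the same strand and the B gene to start within a
    configurable gap downstream of the A gene (reading-direction aware).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .msa import Alignment, SequenceRecord

log = logging.getLogger(__name__)

__all__ = [
    "GeneHit",
    "PairedAlignment",
    "find_gene_pairs",
    "build_paired_alignment",
    "trim_termini",
    "read_gene_hits_gff3",
    "read_gene_hits_tsv",
    "write_gene_hits_tsv",
]

DEFAULT_MAX_GAP_NT = 500


@dataclass(frozen=True)
class GeneHit:
    """One annotated gene on a contig, assigned to family A or B."""

    contig_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    family: str
    sequence_id: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError(f"gene {self.gene_id!r} lacks a contig id")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.family not in {"A", "B"}:
            raise ValueError(f"gene {self.gene_id!r}: family must be 'A' or 'B'")


@dataclass
class PairedAlignment:
    """Row-wise concatenation of an A-region and a B-region."""

    alignment: Alignment
    boundary: int

    def __post_init__(self) -> None:
        if not (0 < self.boundary < self.alignment.ncols):
            raise ValueError("boundary must split the alignment into two regions")

    @property
    def lenA(self) -> int:
        return self.boundary

    @property
    def lenB(self) -> int:
        return self.alignment.ncols - self.boundary


def _downstream_gap(a: GeneHit, b: GeneHit) -> int | None:
    """Nucleotide gap from A's 3' end to B's 5' start in reading direction.

    Returns None when B is not downstream of A on the shared strand.
    """
    if a.strand == "+":
        gap = b.start - a.end
    else:
        gap = a.start - b.end
    return gap if gap >= 0 else None


def find_gene_pairs(
    hits: Iterable[GeneHit],
    mode: str = "adjacent_downstream",
    max_gap_nt: int = DEFAULT_MAX_GAP_NT,
) -> list[tuple[GeneHit, GeneHit]]:
    """Pair A-family and B-family hits by contig co-occurrence or adjacency.

    Contigs with several candidate pairings are resolved by nearest
    separation; unresolved ties are dropped with a warning.
    """
    if mode not in {"same_contig", "adjacent_downstream"}:
        raise ValueError(f"unknown pairing mode: {mode!r}")
    by_contig: dict[str, tuple[list[GeneHit], list[GeneHit]]] = {}
    for h in hits:
        slot = by_contig.setdefault(h.contig_id, ([], []))
        slot[0 if h.family == "A" else 1].append(h)

    pairs: list[tuple[GeneHit, GeneHit]] = []
    for contig in sorted(by_contig):
        a_hits, b_hits = by_contig[contig]
        if not a_hits or not b_hits:
            continue
        if mode == "same_contig":
            if len(a_hits) == 1 and len(b_hits) == 1:
                pairs.append((a_hits[0], b_hits[0]))
            else:
                log.warning(
                    "contig %s: ambiguous co-occurrence (%d A, %d B hits), skipped",
                    contig, len(a_hits), len(b_hits),
                )
            continue
        # adjacent_downstream: score all candidates, greedy nearest-first
        candidates = []
        for a in a_hits:
            for b in b_hits:
                if a.strand != b.strand:
                    continue
                gap = _downstream_gap(a, b)
                if gap is not None and gap <= max_gap_nt:
                    candidates.append((gap, a, b))
        candidates.sort(key=lambda t: t[0])
        used_a: set[str] = set()
        used_b: set[str] = set()
        i = 0
        while i < len(candidates):
            gap, a, b = candidates[i]
            if a.gene_id in used_a or b.gene_id in used_b:
                i += 1
                continue
            ties = [
                c for c in candidates[i:]
                if c[0] == gap
                and c[1].gene_id not in used_a
                and c[2].gene_id not in used_b
            ]
            if len(ties) > 1 and (
                len({c[1].gene_id for c in ties}) < len(ties)
                or len({c[2].gene_id for c in ties}) < len(ties)
            ):
                log.warning(
                    "contig %s: unresolved pairing tie at gap %d nt, dropped", contig, gap
                )
                drop_a = {c[1].gene_id for c in ties}
                drop_b = {c[2].gene_id for c in ties}
                used_a |= drop_a
                used_b |= drop_b
                i += 1
                continue
            pairs.append((a, b))
            used_a.add(a.gene_id)
            used_b.add(b.gene_id)
            i += 1
    return pairs


def build_paired_alignment(
    alnA: Alignment, alnB: Alignment, pairs: list[tuple[str, str]]
) -> PairedAlignment:
    """Concatenate paired rows of two alignments; unpaired rows are excluded.

    ``pairs`` lists (A row id, B row id); each must reference one row in the
    corresponding alignment.
    """
    if not pairs:
        raise ValueError("cannot build a paired alignment from zero pairs")
    idxA = {r.id: i for i, r in enumerate(alnA.records)}
    idxB = {r.id: i for i, r in enumerate(alnB.records)}
    records = []
    for ida, idb in pairs:
        if ida not in idxA:
            raise KeyError(f"pair references unknown A row {ida!r}")
        if idb not in idxB:
            raise KeyError(f"pair references unknown B row {idb!r}")
        ra = alnA.records[idxA[ida]]
        rb = alnB.records[idxB[idb]]
        records.append(
            SequenceRecord(f"{ra.id}|{rb.id}", ra.residues + rb.residues, ra.source)
        )
    return PairedAlignment(Alignment(records), boundary=alnA.ncols)


def trim_termini(
    paired: PairedAlignment,
    trim_a_lead: int = 0,
    trim_a_tail: int = 0,
    trim_b_lead: int = 0,
    trim_b_tail: int = 0,
    contact_support: list[bool] | None = None,
) -> PairedAlignment:
    """Trim terminal columns of each region; interior trimming is rejected.

    With ``contact_support`` given, terminal runs of unsupported columns in
    each region are trimmed instead of the explicit counts.
    """
    lenA, lenB = paired.lenA, paired.lenB
    if contact_support is not None:
        if len(contact_support) != paired.alignment.ncols:
            raise ValueError("contact_support must have one flag per column")
        sup_a = contact_support[:lenA]
        sup_b = contact_support[lenA:]
        trim_a_lead = next((i for i, s in enumerate(sup_a) if s), lenA)
        trim_a_tail = next((i for i, s in enumerate(reversed(sup_a)) if s), 0)
        trim_b_lead = next((i for i, s in enumerate(sup_b) if s), lenB)
        trim_b_tail = next((i for i, s in enumerate(reversed(sup_b)) if s), 0)
    for name, v in [
        ("trim_a_lead", trim_a_lead), ("trim_a_tail", trim_a_tail),
        ("trim_b_lead", trim_b_lead), ("trim_b_tail", trim_b_tail),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if trim_a_lead + trim_a_tail >= lenA or trim_b_lead + trim_b_tail >= lenB:
        raise ValueError("trim specification removes an entire region")
    cols = list(range(trim_a_lead, lenA - trim_a_tail)) + list(
        range(lenA + trim_b_lead, lenA + lenB - trim_b_tail)
    )
    aln = paired.alignment.subset_columns(cols)
    return PairedAlignment(aln, boundary=lenA - trim_a_lead - trim_a_tail)


def _family_from_attrs(attrs: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip().lower() == "family":
                return v.strip()
    return None


def read_gene_hits_gff3(path: str | Path) -> list[GeneHit]:
    """Read the GFF3 subset: seqid, start, end, strand, and a family attribute.

    The protein sequence id is taken from the ID attribute (falling back to
    ``<seqid>_<start>``).
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, _type, start, end, _score, strand, _phase, attrs = fields
            family = _family_from_attrs(attrs)
            if family is None:
                raise ValueError(f"{path}:{lineno}: missing family attribute")
            gene_id = None
            for part in attrs.split(";"):
                if part.strip().startswith("ID="):
                    gene_id = part.strip()[3:]
            gene_id = gene_id or f"{seqid}_{start}"
            hits.append(
                GeneHit(seqid, gene_id, int(start), int(end), strand, family, gene_id)
            )
    return hits


def read_gene_hits_tsv(path: str | Path) -> list[GeneHit]:
    """Read the 6-column dialect: contig, gene_id, start, end, strand, family."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 TSV columns")
            contig, gene_id, start, end, strand, family = fields
            hits.append(
                GeneHit(contig, gene_id, int(start), int(end), strand, family, gene_id)
            )
    return hits


def write_gene_hits_tsv(hits: list[GeneHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# contig\tgene_id\tstart\tend\tstrand\tfamily\n")
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.gene_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.family}\n"
            )
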