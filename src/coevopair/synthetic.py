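"""Ground-truthed synthetic data generators.

Everything here is deterministic per (seed, parameters): toy two-chain
folds with known contact maps, Potts models planted on those maps, Gibbs
sampling of sequence families, and synthetic metagenome contigs carrying
adjacent A+B gene pairs plus decoys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import AA20, ALPHABET, Q
from .coevolution import PottsModel
from .msa import Alignment, SequenceRecord
from .pairing import GeneHit
from .structures import ContactMap

log = logging.getLogger(__name__)

__all__ = [
    "ToyComplex",
    "SyntheticContigSet",
    "make_toy_complex",
    "potts_from_contacts",
    "sample_sequences",
    "make_contigs",
    "inject_redundancy",
    "write_ground_truth",
]

STEP = 3.8  # consecutive-point spacing, Å
MIN_CLASH = 3.5


@dataclass(frozen=True)
class ToyComplex:
    """Two pseudo-chains with a contact map over the concatenated index space."""

    coordsA: np.ndarray
    coordsB: np.ndarray
    true_contacts: ContactMap
    seed: int

    @property
    def lenA(self) -> int:
        return self.coordsA.shape[0]

    @property
    def lenB(self) -> int:
        return self.coordsB.shape[0]

    def all_coords(self) -> np.ndarray:
        return np.vstack([self.coordsA, self.coordsB])


@dataclass(frozen=True)
class SyntheticContigSet:
    """Synthetic contigs: (id, length, gene hits); plus planted-pair truth."""

    contigs: tuple[tuple[str, int], ...]
    hits: tuple[GeneHit, ...]
    planted_pairs: tuple[tuple[str, str], ...]
    decoy_fraction: float


def _compact_walk(n: int, rng: np.random.Generator, bias: float = 0.4) -> np.ndarray:
    """Self-avoiding random walk with a centroid-attraction compaction bias."""
    for _attempt in range(60):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _try in range(300):
                d = rng.normal(size=3)
                centroid = np.mean(pts, axis=0)
                pull = centroid - pts[-1]
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    d = (1 - bias) * d / np.linalg.norm(d) + bias * pull / norm
                d /= np.linalg.norm(d)
                cand = pts[-1] + STEP * d
                prev = np.asarray(pts[:-1])
                if len(prev) == 0 or np.min(
                    np.linalg.norm(prev - cand, axis=1)
                ) > MIN_CLASH:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError(f"failed to build a self-avoiding walk of length {n}")


def _contacts_from_coords(
    coords: np.ndarray, lenA: int, cutoff: float, min_sep: int
) -> frozenset[tuple[int, int]]:
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = (i < lenA) == (j < lenA)
            if same_chain and (j - i) < min_sep:
                continue
            if d[i, j] < cutoff:
                pairs.add((i, j))
    return frozenset(pairs)


def make_toy_complex(
    lenA: int,
    lenB: int,
    seed: int,
    cutoff: float = 8.0,
    min_sep: int = 6,
    min_interchain: int = 3,
    max_retries: int = 40,
) -> ToyComplex:
    """Build a compact two-chain fold with >= ``min_interchain`` interchain contacts."""
    if lenA < 10 or lenB < 10:
        raise ValueError("chain lengths must be >= 10")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        A = _compact_walk(lenA, rng)
        B = _compact_walk(lenB, rng)
        # aim chain B at a random face of chain A, then slide it in
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
        radiusA = np.max(np.linalg.norm(A, axis=1))
        radiusB = np.max(np.linalg.norm(B, axis=1))
        Bshift = B + (radiusA + radiusB + STEP) * direction
        for offset in np.arange(radiusA + radiusB + STEP, 0.0, -0.5):
            Bc = B + offset * direction
            dmin = np.min(
                np.linalg.norm(A[:, None, :] - Bc[None, :, :], axis=2)
            )
            if dmin < MIN_CLASH + 0.3:
                break
            Bshift = Bc
        else:
            continue
        coords = np.vstack([A, Bshift])
        pairs = _contacts_from_coords(coords, lenA, cutoff, min_sep)
        inter = sum(1 for i, j in pairs if i < lenA <= j)
        if inter >= min_interchain:
            return ToyComplex(
                coordsA=A,
                coordsB=Bshift,
                true_contacts=ContactMap(
                    npos=lenA + lenB, pairs=pairs, cutoff=cutoff, min_sep=min_sep
                ),
                seed=seed,
            )
    raise RuntimeError(
        f"could not achieve {min_interchain} interchain contacts in "
        f"{max_retries} retries"
    )


def potts_from_contacts(
    cmap: ContactMap, coupling_strength: float, seed: int, field_scale: float = 0.5
) -> PottsModel:
    """Plant couplings on the contact pairs of ``cmap``.

    Each contact pair gets a coupling block favoring a random one-to-one
    residue pairing (magnitude ``coupling_strength`` on matched pairs,
    -strength/4 elsewhere), producing strong pairwise correlation; fields
    are a random profile.  Gap states carry no energy.
    """
    rng = np.random.default_rng(seed)
    L = cmap.npos
    naa = len(AA20)
    fields = np.zeros((L, Q))
    fields[:, :naa] = rng.normal(scale=field_scale, size=(L, naa))
    fields[:, naa] = -6.0  # gaps effectively absent
    couplings = np.zeros((L, L, Q, Q))
    for i, j in sorted(cmap.pairs):
        if coupling_strength == 0:
            continue
        perm = rng.permutation(naa)
        block = np.full((naa, naa), -coupling_strength / 4.0)
        block[np.arange(naa), perm] = coupling_strength
        couplings[i, j, :naa, :naa] = block
        couplings[j, i, :naa, :naa] = block.T
    return PottsModel(
        fields=fields, couplings=couplings, lambda_field=0.0, lambda_coupling=0.0
    )


def sample_sequences(
    model: PottsModel,
    n: int,
    burn_in: int = 60,
    thin: int = 0,
    seed: int = 0,
    id_prefix: str = "seq",
) -> Alignment:
    """Gibbs-sample ``n`` sequences from a Potts model.

    ``n`` independent chains are run in parallel for ``burn_in`` full sweeps
    (plus ``thin`` extra sweeps) and each chain emits one sequence.  Sparse
    coupling structure is exploited via per-site neighbour lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = model.ncols
    f = model.fields
    # neighbour lists from nonzero coupling blocks
    nonzero = np.abs(model.couplings).sum(axis=(2, 3)) > 0
    neighbours = [np.flatnonzero(nonzero[i]) for i in range(L)]

    # initialize from the per-site field distribution
    logits0 = f - f.max(axis=1, keepdims=True)
    p0 = np.exp(logits0)
    p0 /= p0.sum(axis=1, keepdims=True)
    states = np.empty((n, L), dtype=np.int64)
    for i in range(L):
        states[:, i] = rng.choice(Q, size=n, p=p0[i])

    for _sweep in range(burn_in + thin):
        for i in range(L):
            logits = np.broadcast_to(f[i], (n, Q)).copy()
            for j in neighbours[i]:
                logits += model.couplings[i, j][:, states[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            states[:, i] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    records = [
        SequenceRecord(
            f"{id_prefix}{s:05d}", "".join(ALPHABET[a] for a in states[s])
        )
        for s in range(n)
    ]
    return Alignment(records)


def inject_redundancy(
    aln: Alignment, n_copies: int, seed: int, max_mutations: int = 2
) -> Alignment:
    """Append near-duplicate rows (<= ``max_mutations`` point changes) for filter tests."""
    rng = np.random.default_rng(seed)
    records = list(aln.records)
    for k in range(n_copies):
        src = records[rng.integers(len(aln.records))]
        chars = list(src.residues)
        for _ in range(rng.integers(max_mutations + 1)):
            pos = rng.integers(len(chars))
            chars[pos] = AA20[rng.integers(len(AA20))]
        records.append(SequenceRecord(f"{src.id}_dup{k}", "".join(chars)))
    return Alignment(records)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_contigs(
    pairs: int,
    decoys: int,
    seed: int,
    gene_len_nt: int = 300,
    max_gap_nt: int = 400,
) -> SyntheticContigSet:
    """Plant ``pairs`` adjacent A+B gene pairs and ``decoys`` unpaired contigs.

    Planted pairs are same-strand with B immediately downstream of A within
    ``max_gap_nt``.  Decoys cycle through: lone A, lone B, and an A with a
    reversed-strand B (never paired by the adjacency rule).
    """
    if pairs < 0 or decoys < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, int]] = []
    hits: list[GeneHit] = []
    planted: list[tuple[str, str]] = []

    for k in range(pairs):
        cid = f"contig_p{k:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        margin = int(rng.integers(50, 400))
        gap = int(rng.integers(10, max_gap_nt))
        length = margin * 2 + 2 * gene_len_nt + gap
        a_id, b_id = f"{cid}_A", f"{cid}_B"
        if strand == "+":
            a_start = margin
            a_end = a_start + gene_len_nt - 1
            b_start = a_end + 1 + gap
            b_end = b_start + gene_len_nt - 1
        else:
            b_start = margin
            b_end = b_start + gene_len_nt - 1
            a_start = b_end + 1 + gap
            a_end = a_start + gene_len_nt - 1
        contigs.append((cid, length))
        hits.append(GeneHit(cid, a_id, a_start, a_end, strand, "A", a_id))
        hits.append(GeneHit(cid, b_id, b_start, b_end, strand, "B", b_id))
        planted.append((a_id, b_id))

    for k in range(decoys):
        cid = f"contig_d{k:04d}"
        margin = int(rng.integers(50, 400))
        kind = k % 3
        if kind == 0:  # lone A
            length = margin * 2 + gene_len_nt
            contigs.append((cid, length))
            hits.append(
                GeneHit(cid, f"{cid}_A", margin, margin + gene_len_nt - 1, "+", "A",
                        f"{cid}_A")
            )
        elif kind == 1:  # lone B
            length = margin * 2 + gene_len_nt
            contigs.append((cid, length))
            hits.append(
                GeneHit(cid, f"{cid}_B", margin, margin + gene_len_nt - 1, "+", "B",
                        f"{cid}_B")
            )
        else:  # A with reversed-strand B downstream
            gap = int(rng.integers(10, max_gap_nt))
            length = margin * 2 + 2 * gene_len_nt + gap
            contigs.append((cid, length))
            a_start = margin
            a_end = a_start + gene_len_nt - 1
            b_start = a_end + 1 + gap
            hits.append(
                GeneHit(cid, f"{cid}_A", a_start, a_end, "+", "A", f"{cid}_A")
            )
            hits.append(
                GeneHit(cid, f"{cid}_B", b_start, b_start + gene_len_nt - 1, "-",
                        "B", f"{cid}_B")
            )

    total = pairs + decoys
    return SyntheticContigSet(
        contigs=tuple(contigs),
        hits=tuple(hits),
        planted_pairs=tuple(planted),
        decoy_fraction=decoys / total if total else 0.0,
    )


def write_ground_truth(
    path: str | Path,
    complex_: ToyComplex | None = None,
    contig_set: SyntheticContigSet | None = None,
) -> None:
    """Dump planted truth (contacts, pairs) as JSON for test harnesses."""
    payload: dict = {}
    if complex_ is not None:
        payload["true_contacts"] = sorted(
            [list(p) for p in complex_.true_contacts.pairs]
        )
        payload["lenA"] = complex_.lenA
        payload["lenB"] = complex_.lenB
        payload["seed"] = complex_.seed
    if contig_set is not None:
        payload["planted_pairs"] = [list(p) for p in contig_set.planted_pairs]
        payload["decoy_fraction"] = contig_set.decoy_fraction
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
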