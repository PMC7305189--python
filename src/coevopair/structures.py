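"""Structure parsing, observed contact maps, prediction evaluation and
rigid superposition.

Observed-contact convention: representative points are Cβ (Cα for glycine),
pairs closer than 8 Å with intra-chain sequence separation >= 6; cross-chain
pairs are exempt from the separation rule.  Both knobs are exposed.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coevolution import ContactPrediction

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureCoords",
    "ContactMap",
    "read_structure",
    "contact_map_from_structure",
    "precision_at",
    "interdomain_contacts",
    "model_fit_rc",
    "cofactor_distance",
    "kabsch_superpose",
    "place_cofactor",
    "template_coverage",
    "write_contact_map_tsv",
    "read_contact_map_tsv",
    "contact_map_to_grid",
]


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: tuple[float, float, float]


@dataclass
class StructureCoords:
    """A flat atom list with selector-based access.

    Selectors are ``chain:resnum:atomname`` strings with glob support in
    every field (e.g. ``"B:*:FE*"``).
    """

    atoms: list[Atom]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on atom {a}")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def select(self, selector: str) -> list[Atom]:
        parts = selector.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"selector must be 'chain:resnum:atomname', got {selector!r}"
            )
        chain, resnum, name = parts
        out = [
            a
            for a in self.atoms
            if fnmatch.fnmatch(a.chain, chain)
            and fnmatch.fnmatch(str(a.resnum), resnum)
            and fnmatch.fnmatch(a.name, name)
        ]
        return out

    def select_coords(self, selector: str) -> np.ndarray:
        atoms = self.select(selector)
        if not atoms:
            raise ValueError(f"selector {selector!r} matched no atoms")
        return np.array([a.xyz for a in atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureCoords":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = [
            Atom(a.chain, a.resnum, a.resname, a.name, tuple(R @ np.asarray(a.xyz) + t))
            for a in self.atoms
        ]
        return StructureCoords(new)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resnum, resname), in order of appearance."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.resnum)
            if key not in seen:
                seen[key] = a.resname
                order.append((a.chain, a.resnum, a.resname))
        return order


@dataclass(frozen=True)
class ContactMap:
    """Binary residue-pair set over positions [0, npos)."""

    npos: int
    pairs: frozenset[tuple[int, int]]
    cutoff: float = 8.0
    min_sep: int = 6

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (0 <= i < j < self.npos):
                raise ValueError(f"pair ({i}, {j}) outside [0, {self.npos})")

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


def read_structure(path: str | Path) -> StructureCoords:
    """Read a PDB or mmCIF file (by extension) into a flat atom list.

    HETATM records are included so cofactor atoms are selectable.
    """
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio

    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        f = pdbxio.CIFFile.read(str(path))
        arr = pdbxio.get_structure(f, model=1)
    else:
        f = pdbio.PDBFile.read(str(path))
        arr = f.get_structure(model=1)
    atoms = [
        Atom(
            chain=str(arr.chain_id[k]),
            resnum=int(arr.res_id[k]),
            resname=str(arr.res_name[k]),
            name=str(arr.atom_name[k]),
            xyz=tuple(float(v) for v in arr.coord[k]),
        )
        for k in range(arr.array_length())
    ]
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return StructureCoords(atoms)


def representative_points(
    coords: StructureCoords,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Per-residue representative point: Cβ, or Cα for glycine.

    Residues with no resolvable representative atom are skipped with a
    warning.  Returns the (n, 3) points and their (chain, resnum) keys in
    order of appearance.
    """
    by_res: dict[tuple[str, int], dict[str, Atom]] = {}
    order: list[tuple[str, int]] = []
    resname: dict[tuple[str, int], str] = {}
    for a in coords.atoms:
        key = (a.chain, a.resnum)
        if key not in by_res:
            by_res[key] = {}
            order.append(key)
            resname[key] = a.resname
        by_res[key][a.name] = a
    pts: list[np.ndarray] = []
    keys: list[tuple[str, int]] = []
    for key in order:
        amap = by_res[key]
        want = "CA" if resname[key] == "GLY" else "CB"
        atom = amap.get(want) or amap.get("CA")
        if atom is None:
            # single-atom groups (ions, cofactor fragments) are not residues
            if len(amap) > 1 or resname[key] in {"HOH"}:
                log.warning(
                    "residue %s:%d (%s): no representative atom, skipped",
                    key[0], key[1], resname[key],
                )
            continue
        pts.append(np.asarray(atom.xyz))
        keys.append(key)
    return np.asarray(pts, dtype=float), keys


def contact_map_from_structure(
    coords: StructureCoords, cutoff: float = 8.0, min_sep: int = 6
) -> ContactMap:
    """Representative-point contact map: distance < cutoff, separation >= min_sep.

    Positions are indexed by order of appearance; the separation rule applies
    within one chain only (positional index difference), cross-chain pairs
    are always eligible.
    """
    pts, keys = representative_points(coords)
    n = len(keys)
    if n < 2:
        raise ValueError("need at least two residues with representative atoms")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = keys[i][0] == keys[j][0]
            if same_chain and (j - i) < min_sep:
                continue
            if d[i, j] < cutoff:
                pairs.add((i, j))
    return ContactMap(npos=n, pairs=frozenset(pairs), cutoff=cutoff, min_sep=min_sep)


def precision_at(
    preds: list[ContactPrediction], observed: ContactMap, k: int
) -> float:
    """Fraction of the top-k predictions present in the observed map."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(preds):
        log.warning("k=%d exceeds %d available predictions; evaluating on all", k, len(preds))
        k = len(preds)
    if k == 0:
        raise ValueError("no predictions to evaluate")
    ranked = sorted(preds, key=lambda p: -p.probability)[:k]
    hits = sum(1 for p in ranked if (p.i, p.j) in observed)
    return hits / k


def interdomain_contacts(
    preds: list[ContactPrediction],
    boundaries: dict[str, tuple[int, int]],
    threshold: float = 0.5,
) -> list[tuple[str, ContactPrediction]]:
    """Predictions whose endpoints fall in different named regions.

    ``boundaries`` maps region name -> half-open column range [start, stop);
    the ranges must not overlap.  Returned labels are "REG1-REG2" in the
    order the regions were declared.
    """
    items = list(boundaries.items())
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            (s1, e1), (s2, e2) = items[a][1], items[b][1]
            if max(s1, s2) < min(e1, e2):
                raise ValueError(
                    f"regions {items[a][0]!r} and {items[b][0]!r} overlap"
                )

    def region_of(col: int) -> str | None:
        for name, (s, e) in items:
            if s <= col < e:
                return name
        return None

    out = []
    order = {name: k for k, (name, _) in enumerate(items)}
    for p in preds:
        if p.probability < threshold:
            continue
        ri, rj = region_of(p.i), region_of(p.j)
        if ri is None or rj is None or ri == rj:
            continue
        first, second = sorted((ri, rj), key=order.get)
        out.append((f"{first}-{second}", p))
    return out


def model_fit_rc(
    preds: list[ContactPrediction], model_map: ContactMap, top_n: int
) -> float:
    """Model-fit ratio: satisfied count over summed probability of top-n predictions.

    Native-like models score roughly in the 0.7-1.2 reference band.
    """
    if top_n > len(preds):
        raise ValueError(f"top_n={top_n} exceeds {len(preds)} predictions")
    ranked = sorted(preds, key=lambda p: -p.probability)[:top_n]
    mass = sum(p.probability for p in ranked)
    if mass <= 0:
        raise ValueError("zero probability mass in top predictions")
    satisfied = sum(1 for p in ranked if (p.i, p.j) in model_map)
    return satisfied / mass


def cofactor_distance(
    coords: StructureCoords, group_a: str, group_b: str
) -> float:
    """Minimum pairwise distance (Å) between two atom selections."""
    xa = coords.select_coords(group_a)
    xb = coords.select_coords(group_b)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1).  Degenerate (collinear) point sets are flagged with a
    warning but a solution is still returned.
    """
    P = np.asarray(mobile, dtype=float)
    T = np.asarray(target, dtype=float)
    if P.shape != T.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    cp, ct = P.mean(axis=0), T.mean(axis=0)
    H = (P - cp).T @ (T - ct)
    U, sv, Vt = np.linalg.svd(H)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        log.warning("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cp
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(((moved - T) ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def place_cofactor(
    model: StructureCoords,
    cofactor: StructureCoords,
    anchor_pairs: list[tuple[str, str]],
) -> tuple[StructureCoords, float]:
    """Rigidly place a cofactor by superposing anchor atoms onto the model.

    ``anchor_pairs`` lists (model selector, cofactor-frame selector); each
    selector must match exactly one atom.  Returns the transformed cofactor
    and the anchor RMSD.
    """
    if len(anchor_pairs) < 3:
        raise ValueError("need at least 3 anchor pairs")
    tgt, mob = [], []
    for msel, csel in anchor_pairs:
        ma = model.select(msel)
        ca = cofactor.select(csel)
        if len(ma) != 1:
            raise ValueError(f"model selector {msel!r} matched {len(ma)} atoms")
        if len(ca) != 1:
            raise ValueError(f"cofactor selector {csel!r} matched {len(ca)} atoms")
        tgt.append(ma[0].xyz)
        mob.append(ca[0].xyz)
    R, t, rmsd = kabsch_superpose(np.array(mob), np.array(tgt))
    return cofactor.transformed(R, t), rmsd


def template_coverage(
    preds: list[ContactPrediction],
    template_map: ContactMap,
    mapping: dict[int, int],
    k: int | None = None,
) -> tuple[float, float]:
    """Fraction of top-k predicted contacts covered by a template.

    A prediction is covered when both endpoints map into the template (via
    ``mapping``: query column -> template position) and form a contact
    there.  Returns (coverage, gap_score) with gap_score = 1 - coverage.
    """
    if not preds:
        raise ValueError("empty prediction list")
    if not mapping:
        raise ValueError("empty query-to-template mapping")
    if k is None:
        k = template_map.npos
    ranked = sorted(preds, key=lambda p: -p.probability)[: min(k, len(preds))]
    covered = 0
    for p in ranked:
        ti, tj = mapping.get(p.i), mapping.get(p.j)
        if ti is not None and tj is not None and (ti, tj) in template_map:
            covered += 1
    coverage = covered / len(ranked)
    return coverage, 1.0 - coverage


# ---------------------------------------------------------------------------
# I/O

def write_contact_map_tsv(cmap: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# npos={cmap.npos} cutoff={cmap.cutoff} min_sep={cmap.min_sep}\n")
        for i, j in sorted(cmap.pairs):
            fh.write(f"{i}\t{j}\n")


def read_contact_map_tsv(path: str | Path) -> ContactMap:
    pairs = set()
    npos, cutoff, min_sep = 0, 8.0, 6
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "npos":
                        npos = int(val)
                    elif key == "cutoff":
                        cutoff = float(val)
                    elif key == "min_sep":
                        min_sep = int(val)
                continue
            i, j = map(int, line.split())
            pairs.add((i, j))
    return ContactMap(npos=npos, pairs=frozenset(pairs), cutoff=cutoff, min_sep=min_sep)


def contact_map_to_grid(cmap: ContactMap) -> str:
    """Square-matrix text grid ('.' empty, 'X' contact)."""
    grid = [["."] * cmap.npos for _ in range(cmap.npos)]
    for i, j in cmap.pairs:
        grid[i][j] = grid[j][i] = "X"
    return "\n".join("".join(row) for row in grid)
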