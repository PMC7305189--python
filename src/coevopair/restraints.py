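"""Geometric restraint generation for folding engines.

Restraints are emitted as Rosetta-style constraint text (AtomPair / Angle /
Dihedral lines with HARMONIC / CIRCULARHARMONIC / SIGMOID / BOUNDED function
blocks).  Angle and dihedral parameters are stored in degrees and written in
radians, matching the engine convention; an optional ``#stage=`` suffix
records centroid-only restraints and round-trips through the parser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .coevolution import ContactPrediction
from .structures import StructureCoords, kabsch_superpose

__all__ = [
    "Restraint",
    "ClusterGeometrySpec",
    "CorrinoidSpec",
    "DEFAULT_CLUSTER_SPEC",
    "DEFAULT_CORRINOID_SPEC",
    "DEFAULT_CLUSTER_GROUPS",
    "contact_restraints",
    "extract_cluster_geometry",
    "cluster_restraints",
    "corrinoid_restraints",
    "place_cofactor",
    "write_restraints",
    "read_restraints",
]

# re-exported here because cofactor placement is part of the restraint workflow
from .structures import place_cofactor  # noqa: E402

_KINDS = {
    "harmonic_distance": 2,
    "bounded_distance": 2,
    "sigmoidal_distance": 2,
    "harmonic_angle": 3,
    "circular_harmonic_dihedral": 4,
}


@dataclass(frozen=True)
class Restraint:
    """One typed geometric restraint bound to named atoms.

    ``atoms`` are (atom name, residue number) pairs; ``params`` depend on the
    kind: harmonic (center, width), bounded (lb, ub, sd, rswitch), sigmoid
    (anchor, slope).  Angles/dihedrals are in degrees.
    """

    kind: str
    atoms: tuple[tuple[str, int], ...]
    params: tuple[float, ...]
    stage_tag: str = "all_stages"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if len(self.atoms) != _KINDS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KINDS[self.kind]} atoms, got {len(self.atoms)}"
            )
        if self.kind in {"harmonic_distance", "harmonic_angle",
                         "circular_harmonic_dihedral"}:
            if self.params[1] <= 0:
                raise ValueError(f"{self.kind}: width must be positive")
        if self.stage_tag not in {"all_stages", "centroid_only"}:
            raise ValueError(f"bad stage tag {self.stage_tag!r}")


@dataclass(frozen=True)
class ClusterGeometrySpec:
    """Averaged cluster-coordination geometry from a reference structure.

    Four motif positions each for angles (Cα-Cβ-Sγ) and dihedrals
    (C-Cα-Cβ-Sγ); distances are Sγ-Sγ.
    """

    mean_sg_sg: float
    sg_sg_tol: float
    angles: tuple[float, float, float, float]
    angle_tol: float
    dihedrals: tuple[float, float, float, float]
    dihedral_tol: float
    source: str = ""

    def __post_init__(self) -> None:
        if min(self.sg_sg_tol, self.angle_tol, self.dihedral_tol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class CorrinoidSpec:
    """Cofactor binding restraint parameters.

    ``hydrogen_bonds`` are four (protein atom, protein resnum, cofactor atom,
    distance, tol) entries; ``cys_on`` holds the coordinating-cysteine
    (Sγ-Co distance, tol, Cβ-Sγ-Co angle in degrees, tol) tuple.
    """

    hydrogen_bonds: tuple[tuple[str, int, str, float, float], ...]
    cys_on: tuple[float, float, float, float]
    cys_resnum: int

    def __post_init__(self) -> None:
        if len(self.hydrogen_bonds) != 4:
            raise ValueError("exactly four hydrogen-bond restraints required")
        if len(self.cys_on) != 4:
            raise ValueError("cys_on must be (distance, tol, angle, tol)")


# Reference geometry averaged over both clusters of a 0.94 Å dicluster
# ferredoxin structure; motif positions correspond by order within each
# CxxCxxCxxxCP motif.
DEFAULT_CLUSTER_SPEC = ClusterGeometrySpec(
    mean_sg_sg=6.4,
    sg_sg_tol=0.5,
    angles=(114.6, 116.9, 112.9, 108.9),
    angle_tol=1.0,
    dihedrals=(56.1, -52.7, -71.6, 58.4),
    dihedral_tol=2.3,
    source="2FDN",
)

#: default target cysteine groups, motif order (positions 1-4 of each motif)
DEFAULT_CLUSTER_GROUPS = ((20, 23, 26, 60), (50, 53, 56, 30))

DEFAULT_CORRINOID_SPEC = CorrinoidSpec(
    hydrogen_bonds=(
        ("OG1", 60, "N3B", 2.9, 0.1),
        ("OG1", 66, "O4", 2.7, 0.2),
        ("N", 91, "O4", 3.0, 0.05),
        ("N", 153, "O6R", 3.1, 0.2),
    ),
    cys_on=(2.5, 0.1, 108.0, 5.0),
    cys_resnum=93,
)


def contact_restraints(
    preds: list[ContactPrediction],
    threshold: float,
    form: str = "sigmoid",
    glycine_positions: set[int] | None = None,
    anchor: float = 8.0,
    base_slope: float = 2.0,
) -> list[Restraint]:
    """One distance restraint per prediction above ``threshold``.

    Endpoint atoms are Cβ, or Cα at positions listed in
    ``glycine_positions`` (0-based).  Sigmoid restraints are anchored at
    ``anchor`` Å with slope scaled by the prediction probability; bounded
    restraints span [1.5, 8.0] Å and are tagged centroid-only.
    Residue numbers in the output are 1-based.
    """
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if form not in {"sigmoid", "bounded"}:
        raise ValueError(f"unknown restraint form {form!r}")
    gly = glycine_positions or set()

    def atom(col: int) -> tuple[str, int]:
        return ("CA" if col in gly else "CB", col + 1)

    out = []
    for p in preds:
        if p.probability < threshold:
            continue
        atoms = (atom(p.i), atom(p.j))
        if form == "sigmoid":
            out.append(
                Restraint(
                    "sigmoidal_distance",
                    atoms,
                    (anchor, round(base_slope * p.probability, 6)),
                )
            )
        else:
            out.append(
                Restraint(
                    "bounded_distance",
                    atoms,
                    (1.5, 8.0, 1.0, 0.5),
                    stage_tag="centroid_only",
                )
            )
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _angle(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _res_atom(ref: StructureCoords, resnum: int, name: str) -> np.ndarray:
    for a in ref.atoms:
        if a.resnum == resnum and a.name == name:
            return np.asarray(a.xyz)
    raise ValueError(f"residue {resnum}: missing atom {name}")


def extract_cluster_geometry(
    ref: StructureCoords,
    cluster_cys_groups: tuple[tuple[int, ...], tuple[int, ...]],
    sg_sg_tol: float = 0.5,
    angle_tol: float = 1.0,
    dihedral_tol: float = 2.3,
    source: str = "",
) -> ClusterGeometrySpec:
    """Average coordination geometry over two four-cysteine groups.

    mean_sg_sg averages all six Sγ-Sγ pairs per group over both groups;
    per-motif-position angles (Cα-Cβ-Sγ) and dihedrals (C-Cα-Cβ-Sγ) average
    the two groups' corresponding residues (by order within each group).
    """
    if len(cluster_cys_groups) != 2 or any(len(g) != 4 for g in cluster_cys_groups):
        raise ValueError("expected two groups of four cysteine residue numbers")
    dists = []
    angles = np.zeros((2, 4))
    dihedrals = np.zeros((2, 4))
    for g, group in enumerate(cluster_cys_groups):
        sg = [_res_atom(ref, r, "SG") for r in group]
        for a, b in combinations(range(4), 2):
            dists.append(float(np.linalg.norm(sg[a] - sg[b])))
        for k, r in enumerate(group):
            ca = _res_atom(ref, r, "CA")
            cb = _res_atom(ref, r, "CB")
            c = _res_atom(ref, r, "C")
            angles[g, k] = _angle(ca, cb, sg[k])
            dihedrals[g, k] = _dihedral(c, ca, cb, sg[k])
    # circular mean per motif position for the dihedrals
    rad = np.radians(dihedrals)
    mean_dih = np.degrees(
        np.arctan2(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0))
    )
    return ClusterGeometrySpec(
        mean_sg_sg=float(np.mean(dists)),
        sg_sg_tol=sg_sg_tol,
        angles=tuple(float(x) for x in angles.mean(axis=0)),
        angle_tol=angle_tol,
        dihedrals=tuple(float(x) for x in mean_dih),
        dihedral_tol=dihedral_tol,
        source=source,
    )


def cluster_restraints(
    spec: ClusterGeometrySpec = DEFAULT_CLUSTER_SPEC,
    target_groups: tuple[tuple[int, ...], ...] = DEFAULT_CLUSTER_GROUPS,
) -> list[Restraint]:
    """Restraints enforcing cluster-binding geometry on target cysteines.

    Per group of four: six harmonic Sγ-Sγ distances, four harmonic
    Cα-Cβ-Sγ angles, and four circular-harmonic C-Cα-Cβ-Sγ dihedrals
    (14 restraints per cluster; 28 for the default two clusters).
    """
    out = []
    for group in target_groups:
        if len(group) != 4:
            raise ValueError(f"cluster group must have 4 residues, got {len(group)}")
        for a, b in combinations(group, 2):
            out.append(
                Restraint(
                    "harmonic_distance",
                    (("SG", a), ("SG", b)),
                    (spec.mean_sg_sg, spec.sg_sg_tol),
                )
            )
        for k, r in enumerate(group):
            out.append(
                Restraint(
                    "harmonic_angle",
                    (("CA", r), ("CB", r), ("SG", r)),
                    (spec.angles[k], spec.angle_tol),
                )
            )
        for k, r in enumerate(group):
            out.append(
                Restraint(
                    "circular_harmonic_dihedral",
                    (("C", r), ("CA", r), ("CB", r), ("SG", r)),
                    (spec.dihedrals[k], spec.dihedral_tol),
                )
            )
    return out


def corrinoid_restraints(spec: CorrinoidSpec = DEFAULT_CORRINOID_SPEC) -> list[Restraint]:
    """Cofactor-binding restraints: 4 hydrogen bonds + Sγ-Co distance + Cβ-Sγ-Co angle.

    Cofactor atoms carry residue number 0 (the ligand pseudo-residue).
    """
    out = []
    for pa, resnum, cof_atom, dist, tol in spec.hydrogen_bonds:
        out.append(
            Restraint("harmonic_distance", ((pa, resnum), (cof_atom, 0)), (dist, tol))
        )
    d, dtol, ang, atol = spec.cys_on
    out.append(
        Restraint(
            "harmonic_distance", (("SG", spec.cys_resnum), ("CO", 0)), (d, dtol)
        )
    )
    out.append(
        Restraint(
            "harmonic_angle",
            (("CB", spec.cys_resnum), ("SG", spec.cys_resnum), ("CO", 0)),
            (ang, atol),
        )
    )
    return out


# ---------------------------------------------------------------------------
# Rosetta-style constraint text

_HEADERS = {
    "harmonic_distance": "AtomPair",
    "bounded_distance": "AtomPair",
    "sigmoidal_distance": "AtomPair",
    "harmonic_angle": "Angle",
    "circular_harmonic_dihedral": "Dihedral",
}


def _num(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".")


def _fmt_restraint(r: Restraint, radians: bool) -> str:
    atoms = " ".join(f"{name} {res}" for name, res in r.atoms)
    conv = math.radians if radians else (lambda x: x)
    if r.kind == "harmonic_distance":
        func = f"HARMONIC {_num(r.params[0])} {_num(r.params[1])}"
    elif r.kind == "bounded_distance":
        lb, ub, sd, rswitch = r.params
        func = f"BOUNDED {_num(lb)} {_num(ub)} {_num(sd)} {_num(rswitch)} contact"
    elif r.kind == "sigmoidal_distance":
        func = f"SIGMOID {_num(r.params[0])} {_num(r.params[1])}"
    elif r.kind == "harmonic_angle":
        func = f"HARMONIC {_num(conv(r.params[0]))} {_num(conv(r.params[1]))}"
    else:  # circular_harmonic_dihedral
        func = (
            f"CIRCULARHARMONIC {_num(conv(r.params[0]))} {_num(conv(r.params[1]))}"
        )
    line = f"{_HEADERS[r.kind]} {atoms} {func}"
    if r.stage_tag != "all_stages":
        line += f"  #stage={r.stage_tag}"
    return line


def write_restraints(
    restraints: list[Restraint], path: str | Path, radians: bool = False
) -> None:
    """Write constraint text.

    Angle-type parameters are written in degrees by default so files
    round-trip losslessly; pass ``radians=True`` for engine-native radian
    output (one-way).  The unit is recorded in the file header.
    """
    with open(path, "w") as fh:
        fh.write(f"# angle units: {'radians' if radians else 'degrees'}\n")
        for r in restraints:
            fh.write(_fmt_restraint(r, radians) + "\n")


def read_restraints(path: str | Path) -> list[Restraint]:
    out = []
    in_radians = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("# angle units:"):
                in_radians = line.split(":")[1].strip() == "radians"
                continue
            if not line or line.startswith("#"):
                continue
            conv = math.degrees if in_radians else (lambda x: x)
            stage = "all_stages"
            if "#stage=" in line:
                line, _, tag = line.partition("#stage=")
                stage = tag.strip()
                line = line.strip()
            parts = line.split()
            head = parts[0]
            if head == "AtomPair":
                atoms = ((parts[1], int(parts[2])), (parts[3], int(parts[4])))
                func, fp = parts[5], parts[6:]
                if func == "HARMONIC":
                    out.append(
                        Restraint("harmonic_distance", atoms,
                                  (float(fp[0]), float(fp[1])), stage)
                    )
                elif func == "BOUNDED":
                    out.append(
                        Restraint("bounded_distance", atoms,
                                  tuple(float(x) for x in fp[:4]), stage)
                    )
                elif func == "SIGMOID":
                    out.append(
                        Restraint("sigmoidal_distance", atoms,
                                  (float(fp[0]), float(fp[1])), stage)
                    )
                else:
                    raise ValueError(f"{path}:{lineno}: unknown function {func!r}")
            elif head == "Angle":
                atoms = tuple(
                    (parts[1 + 2 * k], int(parts[2 + 2 * k])) for k in range(3)
                )
                fp = parts[8:]
                out.append(
                    Restraint(
                        "harmonic_angle", atoms,
                        (conv(float(fp[0])), conv(float(fp[1]))),
                        stage,
                    )
                )
            elif head == "Dihedral":
                atoms = tuple(
                    (parts[1 + 2 * k], int(parts[2 + 2 * k])) for k in range(4)
                )
                fp = parts[10:]
                out.append(
                    Restraint(
                        "circular_harmonic_dihedral", atoms,
                        (conv(float(fp[0])), conv(float(fp[1]))),
                        stage,
                    )
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown restraint type {head!r}")
    return out
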