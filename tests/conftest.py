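import numpy as np
import pytest

from coevopair.msa import Alignment, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(nrows: int, ncols: int, seed: int, gap_frac: float = 0.0) -> Alignment:
    rng = np.random.default_rng(seed)
    records = []
    for s in range(nrows):
        chars = rng.choice(list(AA), size=ncols)
        if gap_frac:
            mask = rng.random(ncols) < gap_frac
            chars = np.where(mask, "-", chars)
        records.append(SequenceRecord(f"s{s}", "".join(chars)))
    return Alignment(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_alignment():
    return random_alignment(5, 20, seed=7)


def make_pdb_text(atoms):
    """Minimal PDB ATOM/HETATM text from (record, serial, name, resname, chain,
    resnum, x, y, z) tuples."""
    lines = []
    for rec, serial, name, resname, chain, resnum, x, y, z in atoms:
        nm = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"{rec:<6s}{serial:>5d} {nm}{'':1s}{resname:>3s} {chain}{resnum:>4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{name[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
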