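import numpy as np
import pytest

from fodm import GeneratorConfig, StructureUnit, gen_toy_complex, gen_unit
from fodm.structure_io import ResidueModel


def pdb_atom(serial, name, resname, chain, resseq, x, y, z,
             element=None, altloc=" ", occ=1.00):
    """One fixed-column ATOM record."""
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture
def minimal_pdb(tmp_path):
    """Smallest well-formed input: GLY A1 and ALA A2."""
    lines = [
        pdb_atom(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom(2, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0, element="C"),
        pdb_atom(3, "C", "GLY", "A", 1, 2.0, 0.0, 0.0),
        pdb_atom(4, "O", "GLY", "A", 1, 2.5, 1.0, 0.0),
        pdb_atom(5, "N", "ALA", "A", 2, 3.0, 0.0, 0.0),
        pdb_atom(6, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0, element="C"),
        pdb_atom(7, "C", "ALA", "A", 2, 5.0, 0.0, 0.0),
        pdb_atom(8, "O", "ALA", "A", 2, 5.5, 1.0, 0.0),
        pdb_atom(9, "CB", "ALA", "A", 2, 4.0, 1.5, 0.0, element="C"),
        "END",
    ]
    p = tmp_path / "minimal.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


def make_residue(aa="ALA", chain="A", seq=1, xyz=(0.0, 0.0, 0.0), H=None):
    """Single-pseudo-atom residue at a given effective position."""
    xyz = np.asarray(xyz, dtype=float)
    r = ResidueModel(chain_id=chain, seq_num=seq, icode="", aa=aa,
                     atoms=[("C", "CA", xyz)], H=H)
    r.effective_xyz = xyz
    return r


def make_unit(coords, H=None, aa="ALA", chain="A", ss_bonds=()):
    """Unit of single-atom residues at the given coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    hs = [None] * len(coords) if H is None else list(np.broadcast_to(H, len(coords)))
    residues = [make_residue(aa=aa, chain=chain, seq=i + 1, xyz=c, H=h)
                for i, (c, h) in enumerate(zip(coords, hs))]
    return StructureUnit(residues=residues, ss_bonds=list(ss_bonds),
                         source_id="test")


@pytest.fixture
def micelle_unit():
    return gen_unit(GeneratorConfig(n_residues=150, seed=11, mode="ideal_micelle"))


@pytest.fixture
def toy_complex():
    """Two 60-residue chains close enough to touch (gap 8 A < 9 A cutoff)."""
    cfg = GeneratorConfig(n_residues=60, sigmas=(10.0, 8.0, 7.0))
    return gen_toy_complex([cfg, cfg], gap=8.0, seed=42)


def random_rigid_transform(rng):
    """A uniformly random rotation plus a translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=50.0, size=3)
    return Q, t


def transform_unit(unit, Q, t):
    out = []
    for r in unit.residues:
        rr = make_residue(aa=r.aa, chain=r.chain_id, seq=r.seq_num,
                          xyz=r.effective_xyz @ Q.T + t, H=r.H)
        out.append(rr)
    return StructureUnit(residues=out, ss_bonds=list(unit.ss_bonds),
                         source_id=unit.source_id)
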