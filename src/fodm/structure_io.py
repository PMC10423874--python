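"""Structure parsing and writing.

Reads PDB/mmCIF coordinate files into :class:`StructureUnit` objects — one
effective atom per standard amino-acid residue — and writes units back out as
fixed-column PDB so synthetic fixtures round-trip through the same parser.
Parsing is delegated to gemmi; this module only applies the residue-level
policies (first model, altloc resolution, hetero/nucleic exclusion).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import gemmi
import numpy as np

from .errors import EmptyUnitError, ParseError, UnknownResidueError

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid three-letter codes
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: common modified residues mapped to their parent under the lenient policy
SUBSTITUTIONS: Mapping[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",  # hydroxyproline
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

#: backbone atoms excluded from the side-chain centroid
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

ResidueKey = tuple[str, int, str]  # (chain_id, seq_num, icode)


@dataclass
class ResidueModel:
    """One amino-acid residue reduced to a single interaction site.

    ``effective_xyz`` is the side-chain heavy-atom centroid (Cα fallback for
    glycine or residues with no resolved side chain); ``H`` is the intrinsic
    hydrophobicity in [0, 1], unset until a scale is assigned.
    """

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[tuple[str, str, np.ndarray]]  # (element, atom name, xyz)
    effective_xyz: np.ndarray | None = None
    H: float | None = None
    ca_fallback: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.chain_id}{self.seq_num} has no atoms")
        if self.H is not None and not (0.0 <= self.H <= 1.0):
            raise ValueError(f"H={self.H} outside [0,1]")


@dataclass
class StructureUnit:
    """An ordered residue list forming one analysis unit (complex, chain, domain)."""

    residues: list[ResidueModel]
    ss_bonds: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    source_id: str = ""
    skipped: list[str] = field(default_factory=list)  # excluded entities, logged

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue identities in unit")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> dict[str, list[int]]:
        """Map chain_id -> indices of its residues (in unit order)."""
        out: dict[str, list[int]] = {}
        for i, r in enumerate(self.residues):
            out.setdefault(r.chain_id, []).append(i)
        return out

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self._index[key]
        except AttributeError:
            self._index = {r.key: i for i, r in enumerate(self.residues)}
            return self._index[key]

    def effective_coords(self) -> np.ndarray:
        """(N, 3) array of effective-atom positions."""
        return np.asarray([r.effective_xyz for r in self.residues], dtype=float)

    def hydrophobicity(self) -> np.ndarray:
        h = [r.H for r in self.residues]
        if any(v is None for v in h):
            raise ValueError("hydrophobicity not assigned; call assign_hydrophobicity")
        return np.asarray(h, dtype=float)

    def subunit(self, indices: Sequence[int], source_id: str | None = None) -> "StructureUnit":
        """A new unit containing the given residues, SS bonds restricted accordingly."""
        residues = [self.residues[i] for i in indices]
        keys = {r.key for r in residues}
        bonds = [(a, b) for a, b in self.ss_bonds if a in keys and b in keys]
        return StructureUnit(residues=residues, ss_bonds=bonds,
                             source_id=source_id or self.source_id)


def effective_atom(residue: ResidueModel) -> np.ndarray:
    """Side-chain heavy-atom centroid; Cα for glycine or missing side chains.

    Hydrogens and backbone atoms (N, CA, C, O, OXT) are excluded from the mean.
    """
    side = [xyz for el, name, xyz in residue.atoms
            if name not in BACKBONE_ATOMS and el not in ("H", "D")]
    if side:
        residue.ca_fallback = False
        return np.mean(np.asarray(side, dtype=float), axis=0)
    ca = [xyz for _el, name, xyz in residue.atoms if name == "CA"]
    if not ca:
        raise ValueError(
            f"residue {residue.aa} {residue.chain_id}{residue.seq_num} has neither "
            "side-chain atoms nor CA"
        )
    if residue.aa != "GLY":
        logger.debug("residue %s %s%d has no side-chain atoms; using CA",
                     residue.aa, residue.chain_id, residue.seq_num)
    residue.ca_fallback = True
    return np.asarray(ca[0], dtype=float)


def load_scale(name_or_path: str = "kyte_doolittle") -> dict[str, float]:
    """Load a hydrophobicity scale and min-max normalize it to [0, 1].

    ``name_or_path`` is a bundled scale name or a path to a two-column TSV
    (three-letter residue code, value).
    """
    p = Path(name_or_path)
    if not p.exists():
        ref = importlib.resources.files("fodm") / "data" / "scales" / f"{name_or_path}.tsv"
        if not ref.is_file():
            raise FileNotFoundError(f"no such hydrophobicity scale: {name_or_path}")
        text = ref.read_text()
    else:
        text = p.read_text()
    raw: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, value = line.split("\t")
        raw[code.upper()] = float(value)
    missing = STANDARD_AA - raw.keys()
    if missing:
        raise ValueError(f"scale does not cover standard residues: {sorted(missing)}")
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {k: 1.0 for k in raw}
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


def assign_hydrophobicity(
    unit: StructureUnit,
    scale: str | Mapping[str, float] = "kyte_doolittle",
    policy: Literal["lenient", "strict"] = "lenient",
) -> StructureUnit:
    """Set each residue's intrinsic hydrophobicity H from its amino-acid code.

    Under the lenient policy, modified residues are mapped to their parent
    (e.g. MSE -> MET); under strict, unknown codes raise. Idempotent and
    independent of residue order.
    """
    table = load_scale(scale) if isinstance(scale, str) else dict(scale)
    for r in unit.residues:
        code = r.aa
        if code not in table:
            if policy == "lenient" and code in SUBSTITUTIONS:
                code = SUBSTITUTIONS[code]
            else:
                raise UnknownResidueError(
                    f"residue code {r.aa!r} at {r.chain_id}{r.seq_num} not in scale"
                )
        r.H = float(table[code])
    return unit


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by first seen."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return list(by_name.values())


def load_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    policy: Literal["lenient", "strict"] = "lenient",
    scale: str | Mapping[str, float] | None = "kyte_doolittle",
) -> StructureUnit:
    """Parse a coordinate file into a StructureUnit.

    Policies: first coordinate model only; one residue per standard amino
    acid (lenient policy also accepts tabulated substitutions such as MSE);
    waters, ligands and nucleic-acid chains are excluded and recorded in
    ``unit.skipped``; alternate locations resolved to the highest-occupancy
    conformer. When ``scale`` is not None, intrinsic hydrophobicity is
    assigned immediately.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyUnitError(f"{path}: no coordinate models")
    if len(st) > 1:
        logger.info("%s: %d models present; keeping the first", path.name, len(st))

    model = st[0]
    residues: list[ResidueModel] = []
    skipped: list[str] = []
    for chain in model:
        for res in chain:
            name = res.name.upper()
            if name in STANDARD_AA or (policy == "lenient" and name in SUBSTITUTIONS):
                atoms = [(a.element.name, a.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                         for a in _resolve_altlocs(res)]
                icode = res.seqid.icode.strip()
                rm = ResidueModel(chain_id=chain.name, seq_num=res.seqid.num,
                                  icode=icode, aa=name, atoms=atoms)
                rm.effective_xyz = effective_atom(rm)
                residues.append(rm)
            else:
                skipped.append(f"{chain.name}/{res.seqid.num} {name}")
    if not residues:
        raise EmptyUnitError(f"{path}: no standard amino-acid residues found")
    if skipped:
        logger.info("%s: skipped %d non-protein entities", path.name, len(skipped))
    n_fallback = sum(1 for r in residues if r.ca_fallback and r.aa != "GLY")
    if n_fallback:
        logger.warning("%s: %d non-glycine residues have no resolved side-chain "
                       "atoms; using CA as effective atom", path.name, n_fallback)

    keys = {}
    for r in residues:
        keys[r.key] = r
    ss_bonds: list[tuple[ResidueKey, ResidueKey]] = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Disulf:
            continue
        k1 = (con.partner1.chain_name, con.partner1.res_id.seqid.num,
              con.partner1.res_id.seqid.icode.strip())
        k2 = (con.partner2.chain_name, con.partner2.res_id.seqid.num,
              con.partner2.res_id.seqid.icode.strip())
        if k1 in keys and k2 in keys:
            ss_bonds.append((k1, k2))
        else:
            logger.warning("SSBOND endpoint outside parsed residues: %s-%s", k1, k2)

    unit = StructureUnit(residues=residues, ss_bonds=ss_bonds,
                         source_id=st.name or path.stem, skipped=skipped)
    if scale is not None:
        assign_hydrophobicity(unit, scale=scale, policy=policy)
    return unit


_COORD_LIMIT = 9999.999  # PDB %8.3f field


def write_pdb(unit: StructureUnit, path: str | Path) -> Path:
    """Write a unit as fixed-column PDB with ATOM and SSBOND records."""
    if len(unit) == 0:
        raise ValueError("cannot write an empty unit")
    for r in unit.residues:
        for _el, _name, xyz in r.atoms:
            if np.any(np.abs(xyz) > _COORD_LIMIT) or np.any(xyz <= -1000.0):
                raise ValueError(
                    f"coordinate {xyz} of residue {r.chain_id}{r.seq_num} exceeds "
                    "the PDB fixed-column field width"
                )
    st = gemmi.Structure()
    st.name = unit.source_id or "unit"
    model = gemmi.Model("1")
    for chain_id, idx in unit.chains.items():
        chain = gemmi.Chain(chain_id)
        for i in idx:
            r = unit.residues[i]
            res = gemmi.Residue()
            res.name = r.aa
            res.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
            res.het_flag = "A"
            for el, name, xyz in r.atoms:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)

    by_key = {r.key: r for r in unit.residues}
    for n, (k1, k2) in enumerate(unit.ss_bonds, start=1):
        con = gemmi.Connection()
        con.name = f"disulf{n}"
        con.type = gemmi.ConnectionType.Disulf
        addrs = []
        for k in (k1, k2):
            r = by_key[k]
            names = [name for _el, name, _xyz in r.atoms]
            atom_name = "SG" if "SG" in names else names[0]
            addrs.append(gemmi.AtomAddress(k[0], gemmi.SeqId(k[1], k[2] or " "),
                                           r.aa, atom_name, "\0"))
        con.partner1, con.partner2 = addrs
        st.connections.append(con)

    path = Path(path)
    path.write_text(st.make_pdb_string())
    return path
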