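"""Structure input/output with author numbering preserved.

Thin layer over gemmi that flattens a coordinate file into plain records:
per-chain lists of polymer residues plus a separate ligand list for HETATM
groups.  All residue numbers exposed to users are author numbers (the
depositors' numbering, e.g. the pseudo P-loop at 151-158), 1-based and
inclusive.  Alternate locations are collapsed to the highest-occupancy
conformer, hydrogens are dropped on read, and waters are excluded from the
ligand list by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

from ploopkit.errors import (
    ChainLookupError,
    EmptyModelError,
    FormatError,
    StructureIOError,
)

AA3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: non-standard residues still treated as polymer (sequence letter 'X'
#: unless an alias table maps them, e.g. MSE -> M)
NONSTANDARD_POLYMER = {"MSE"}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(eq=False)
class AtomRecord:
    """A single heavy atom."""

    atom_name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(eq=False)
class ResidueRecord:
    """One residue (polymer or ligand) with its atoms."""

    chain_id: str
    auth_seq_id: int
    res_name: str
    one_letter: str = "X"
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_id, self.insertion_code)


@dataclass
class StructureModel:
    """Flattened single-model structure: polymer chains plus ligands."""

    entry_id: str = ""
    resolution: float | None = None
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    ligands: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for residues in self.chains.values():
            residues.sort(key=lambda r: (r.auth_seq_id, r.insertion_code))

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainLookupError(f"no chain {chain_id!r} in model {self.entry_id!r}") from None

    def n_polymer_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def require_polymer(self) -> "StructureModel":
        """Raise if the model carries no polymer residues (e.g. a ligand-only file)."""
        if self.n_polymer_residues() == 0:
            raise EmptyModelError(f"model {self.entry_id!r} has zero protein residues")
        return self

    def find_residue(self, chain_id: str, auth_seq_id: int, insertion_code: str = "") -> ResidueRecord:
        for res in self.chain(chain_id):
            if res.auth_seq_id == auth_seq_id and res.insertion_code == insertion_code:
                return res
        raise ChainLookupError(
            f"no residue {auth_seq_id}{insertion_code} in chain {chain_id!r}"
        )


def _sniff_format(path: Path) -> str:
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site" in head:
        return "mmcif"
    return "pdb"


def _resolve_format(path: Path, format: str) -> str:
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            return "pdb"
        if suffix in {".cif", ".mmcif"}:
            return "mmcif"
        return _sniff_format(path)
    if format not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown structure format {format!r}")
    return format


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer per atom name (tie: first altloc id)."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.atom_name not in by_name:
            by_name[a.atom_name] = a
            order.append(a.atom_name)
        else:
            best = by_name[a.atom_name]
            if (a.occupancy, _altloc_rank(a.altloc)) > (best.occupancy, _altloc_rank(best.altloc)):
                by_name[a.atom_name] = a
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins ties; lexicographically first altloc must win, so negate
    return -ord(altloc) if altloc else 1.0


def _mmcif_resolution(path: Path) -> float | None:
    """Resolution from _refine/_reflns tags (pair or loop form)."""
    try:
        block = gemmi.cif.read(str(path)).sole_block()
    except (RuntimeError, ValueError):
        return None
    for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
        for value in block.find_values(tag):
            try:
                return float(value)
            except ValueError:
                continue
    return None


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The first model is used.  HETATM residues (other than water) are routed
    to ``ligands``; hydrogens are dropped; alternate locations are collapsed
    to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.is_file():
        raise StructureIOError(f"cannot read structure file: {path}")
    fmt = _resolve_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    resolution = float(st.resolution) if st.resolution > 0 else None
    if resolution is None and fmt == "mmcif":
        resolution = _mmcif_resolution(path)
    model = StructureModel(entry_id=st.name, resolution=resolution)
    if len(st) == 0:
        return model
    gmodel = st[0]
    for gchain in gmodel:
        for gres in gchain:
            res_name = gres.name.strip()
            if res_name in _WATER_NAMES:
                continue
            atoms = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    AtomRecord(
                        atom_name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        altloc=ga.altloc if ga.altloc else "",
                        occupancy=min(max(float(ga.occ), 0.0), 1.0),
                        is_hetero=(gres.het_flag == "H"),
                    )
                )
            if not atoms:
                continue
            atoms = _collapse_altlocs(atoms)
            is_polymer = gres.het_flag != "H" or res_name in NONSTANDARD_POLYMER
            record = ResidueRecord(
                chain_id=gchain.name,
                auth_seq_id=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_name=res_name,
                one_letter=AA3TO1.get(res_name, "X"),
                atoms=atoms,
            )
            if is_polymer:
                model.chains.setdefault(gchain.name, []).append(record)
            else:
                model.ligands.append(record)
    for residues in model.chains.values():
        residues.sort(key=lambda r: (r.auth_seq_id, r.insertion_code))
    return model


def extract_chain_sequence(
    model: StructureModel,
    chain_id: str,
    aliases: Mapping[str, str] | None = None,
) -> tuple[str, dict[int, int]]:
    """One-letter sequence of a chain plus 1-based index -> author number map.

    Non-standard residues become ``'X'`` unless ``aliases`` maps their
    three-letter code (e.g. ``{"MSE": "M"}``).
    """
    model.require_polymer()
    residues = model.chain(chain_id)
    letters = []
    mapping: dict[int, int] = {}
    for i, res in enumerate(residues, start=1):
        letter = res.one_letter
        if aliases and res.res_name in aliases:
            letter = aliases[res.res_name]
        letters.append(letter)
        mapping[i] = res.auth_seq_id
    return "".join(letters), mapping


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.entry_id or "XXXX"
    if model.resolution is not None:
        st.resolution = float(model.resolution)
    gmodel = gemmi.Model("1")

    def add_residue(gchain: gemmi.Chain, res: ResidueRecord, hetero_default: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.auth_seq_id, res.insertion_code or " ")
        gres.het_flag = "H" if hetero_default else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.altloc = a.altloc if a.altloc else "\0"
            gres.add_atom(ga)
        gchain.add_residue(gres)

    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            add_residue(gchain, res, hetero_default=False)
        gmodel.add_chain(gchain)
    # ligands appended to their author chain (created if absent)
    lig_chains: dict[str, gemmi.Chain] = {}
    for res in model.ligands:
        cid = res.chain_id or "Z"
        if cid in [c.name for c in gmodel]:
            gchain = next(c for c in gmodel if c.name == cid)
        else:
            gchain = lig_chains.get(cid)
            if gchain is None:
                gchain = gemmi.Chain(cid)
                lig_chains[cid] = gchain
        add_residue(gchain, res, hetero_default=True)
    for gchain in lig_chains.values():
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> Path:
    """Write a model as PDB or mmCIF; round-trips numbering and coordinates
    to PDB precision (1e-3 Å)."""
    path = Path(path)
    fmt = _resolve_format(path, format) if format == "auto" else format
    if fmt not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown structure format {fmt!r}")
    st = _to_gemmi(model)
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            doc = st.make_mmcif_document()
            block = doc.sole_block()
            if model.resolution is not None:
                # gemmi only emits _refine when refinement metadata exists
                block.set_pair("_refine.entry_id", st.name)
                block.set_pair("_refine.ls_d_res_high", f"{model.resolution:g}")
            doc.write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise StructureIOError(f"cannot write structure to {path}: {exc}") from exc
    return path


def iter_chain_residues(model: StructureModel) -> Iterable[tuple[str, list[ResidueRecord]]]:
    return model.chains.items()
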