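"""Loop grafting: replace an acceptor pseudo-loop backbone with a donor
P-loop backbone positioned by rigid superposition.

This is the computational analogue of rebuilding a degenerate loop with the
backbone of a functional homologue: the donor loop (by default the A-subunit
P-loop, author residues 232-239) is superposed into the acceptor frame (the
pseudo P-loop, author residues 151-158) using either the Cα atoms of the
flanking residues (``flank_window``, deterministic, default) or all
alignable Cα pairs of the two chains (``global_ca``, the whole-subunit
superposition of homologous chains).  Only backbone atoms (N, CA, C, O) and
CB are transplanted; grafted residues take the donor sequence with side
chains truncated at CB, and every atom outside the grafted range is left
bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ploopkit.errors import AtomError, SpecError
from ploopkit.geometry import (
    abego_classify,
    backbone_torsions,
    kabsch_superpose,
    virtual_cbeta,
)
from ploopkit.ligandfit import DEFAULT_CLASH_SCALE, count_clashes
from ploopkit.motif import MotifDefinition, orientation_feature, torsion_pattern_matches
from ploopkit.structio import AtomRecord, ResidueRecord, StructureModel, AA3TO1

#: peptide C-N splice bonds must fall within this window (Å) for the graft
#: junctions to count as continuous
JUNCTION_BOND = 1.33
JUNCTION_TOL = 0.15

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class GraftSpec:
    """Donor/acceptor ranges (author-numbered, inclusive) and anchor mode."""

    donor: StructureModel
    donor_chain: str
    donor_range: tuple[int, int] = (232, 239)
    acceptor: StructureModel = None  # type: ignore[assignment]
    acceptor_chain: str = "A"
    acceptor_range: tuple[int, int] = (151, 158)
    anchor_mode: str = "flank_window"  # or "global_ca"
    flank_k: int = 4

    def __post_init__(self) -> None:
        d_len = self.donor_range[1] - self.donor_range[0] + 1
        a_len = self.acceptor_range[1] - self.acceptor_range[0] + 1
        if d_len != a_len:
            raise SpecError(f"donor range length {d_len} != acceptor range length {a_len}")
        if d_len < 1:
            raise SpecError("empty graft range")
        if self.anchor_mode not in {"flank_window", "global_ca"}:
            raise SpecError(f"unknown anchor mode {self.anchor_mode!r}")
        if self.flank_k < 1:
            raise SpecError("flank window must span at least one residue")


@dataclass
class GraftReport:
    loop_abego: str
    pattern_retained: bool
    junction_bond_lengths: tuple[float | None, float | None]
    continuity_ok: bool
    clash_count: int
    anchor_rmsd: float
    orientation_value: float | None
    orientation_ok: bool
    anchor_mode: str = "flank_window"
    n_anchor_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "loop_abego": self.loop_abego,
            "pattern_retained": self.pattern_retained,
            "junction_bond_lengths": list(self.junction_bond_lengths),
            "continuity_ok": self.continuity_ok,
            "clash_count": self.clash_count,
            "anchor_rmsd": self.anchor_rmsd,
            "orientation_value": self.orientation_value,
            "orientation_ok": self.orientation_ok,
            "anchor_mode": self.anchor_mode,
            "n_anchor_pairs": self.n_anchor_pairs,
        }


def _range_indices(residues: list[ResidueRecord], auth_range: tuple[int, int]) -> list[int]:
    lo, hi = auth_range
    idx = [i for i, r in enumerate(residues) if lo <= r.auth_seq_id <= hi and not r.insertion_code]
    expected = hi - lo + 1
    if len(idx) != expected:
        raise SpecError(
            f"range {lo}-{hi}: found {len(idx)} residues, expected {expected}"
        )
    if idx != list(range(idx[0], idx[0] + expected)):
        raise SpecError(f"range {lo}-{hi} is not contiguous in chain order")
    return idx


def _ca(residues: list[ResidueRecord], index: int) -> np.ndarray:
    atom = residues[index].atom("CA")
    if atom is None:
        raise AtomError(
            f"residue {residues[index].chain_id}/{residues[index].auth_seq_id} lacks CA"
        )
    return atom.coords


def _anchor_pairs(spec: GraftSpec) -> tuple[np.ndarray, np.ndarray]:
    donor_res = spec.donor.chain(spec.donor_chain)
    accept_res = spec.acceptor.chain(spec.acceptor_chain)
    d_idx = _range_indices(donor_res, spec.donor_range)
    a_idx = _range_indices(accept_res, spec.acceptor_range)
    if spec.anchor_mode == "flank_window":
        k = spec.flank_k
        if d_idx[0] < k or a_idx[0] < k:
            raise SpecError(f"need {k} flanking residues before both ranges")
        if d_idx[-1] + k >= len(donor_res) or a_idx[-1] + k >= len(accept_res):
            raise SpecError(f"need {k} flanking residues after both ranges")
        offsets = list(range(-k, 0)) + list(range(1, k + 1))
        mobile = np.array([_ca(donor_res, d_idx[0] + o if o < 0 else d_idx[-1] + o) for o in offsets])
        reference = np.array(
            [_ca(accept_res, a_idx[0] + o if o < 0 else a_idx[-1] + o) for o in offsets]
        )
        return mobile, reference
    # global_ca: all alignable Cα pairs from a global sequence alignment
    from ploopkit.geometry import _aligned_pairs_by_sequence

    pairs = _aligned_pairs_by_sequence(
        spec.donor, spec.donor_chain, spec.acceptor, spec.acceptor_chain
    )
    donor_by_auth = {r.auth_seq_id: r for r in donor_res if not r.insertion_code}
    accept_by_auth = {r.auth_seq_id: r for r in accept_res if not r.insertion_code}
    mobile, reference = [], []
    for d_auth, a_auth in pairs:
        d_atom = donor_by_auth.get(d_auth)
        a_atom = accept_by_auth.get(a_auth)
        if d_atom is None or a_atom is None:
            continue
        d_ca, a_ca = d_atom.atom("CA"), a_atom.atom("CA")
        if d_ca is None or a_ca is None:
            continue
        mobile.append(d_ca.coords)
        reference.append(a_ca.coords)
    return np.array(mobile), np.array(reference)


def graft_loop(spec: GraftSpec) -> tuple[StructureModel, GraftReport]:
    """Transplant the donor loop backbone into the acceptor structure.

    Returns the new model and a report with the recomputed loop ABEGO,
    junction bond lengths, clash count against the rest of the structure,
    anchor RMSD and orientation feature of the new loop.
    """
    superposition = kabsch_superpose(*_anchor_pairs(spec))

    new_model = copy.deepcopy(spec.acceptor)
    accept_res = new_model.chain(spec.acceptor_chain)
    a_idx = _range_indices(accept_res, spec.acceptor_range)
    donor_res = spec.donor.chain(spec.donor_chain)
    d_idx = _range_indices(donor_res, spec.donor_range)

    for a_i, d_i in zip(a_idx, d_idx):
        donor = donor_res[d_i]
        target = accept_res[a_i]
        new_atoms: list[AtomRecord] = []
        for name in _BACKBONE_NAMES:
            atom = donor.atom(name)
            if atom is None:
                if name == "O":
                    continue  # carbonyl O tolerated missing in donor
                raise AtomError(
                    f"donor residue {donor.chain_id}/{donor.auth_seq_id} lacks {name}"
                )
            new_atoms.append(
                AtomRecord(name, atom.element, superposition.apply(atom.coords))
            )
        if donor.res_name != "GLY":
            cb = donor.atom("CB")
            if cb is not None:
                cb_coords = superposition.apply(cb.coords)
            else:
                placed = {a.atom_name: a.coords for a in new_atoms}
                cb_coords = virtual_cbeta(placed["N"], placed["CA"], placed["C"])
            new_atoms.append(AtomRecord("CB", "C", cb_coords))
        accept_res[a_i] = ResidueRecord(
            chain_id=target.chain_id,
            auth_seq_id=target.auth_seq_id,
            insertion_code=target.insertion_code,
            res_name=donor.res_name,
            one_letter=AA3TO1.get(donor.res_name, "X"),
            atoms=new_atoms,
        )

    report = validate_graft(
        new_model,
        chain_id=spec.acceptor_chain,
        loop_range=spec.acceptor_range,
    )
    report.anchor_rmsd = superposition.rmsd
    report.anchor_mode = spec.anchor_mode
    report.n_anchor_pairs = superposition.n_pairs
    return new_model, report


def validate_graft(
    model: StructureModel,
    chain_id: str,
    loop_range: tuple[int, int],
    expected_pattern: str = "EBBGAGAA",
    torsion_tolerance_deg: float | None = None,
    clash_scale: float = DEFAULT_CLASH_SCALE,
    definition: MotifDefinition | None = None,
) -> GraftReport:
    """Re-derive all graft quality flags for a loop range of a model.

    Checks torsion-pattern retention (exact or tolerance mode), junction
    C-N bond lengths at both splice points, heavy-atom clashes of the loop
    against the rest of the structure, and the orientation feature.
    """
    definition = definition or MotifDefinition.walker_a()
    residues = model.chain(chain_id)
    idx = _range_indices(residues, loop_range)
    n_loop = len(idx)
    if len(expected_pattern) != n_loop:
        raise SpecError(
            f"expected pattern length {len(expected_pattern)} != loop length {n_loop}"
        )

    torsions = backbone_torsions(residues)
    loop_torsions = torsions[idx[0] : idx[-1] + 1]
    loop_abego = abego_classify(torsions)[idx[0] : idx[-1] + 1]
    pattern_retained = torsion_pattern_matches(
        loop_abego, loop_torsions, expected_pattern, torsion_tolerance_deg
    )

    def junction(i_before: int, i_after: int) -> float | None:
        if i_before < 0 or i_after >= len(residues):
            return None
        c_atom = residues[i_before].atom("C")
        n_atom = residues[i_after].atom("N")
        if c_atom is None or n_atom is None:
            return None
        return float(np.linalg.norm(n_atom.coords - c_atom.coords))

    j_in = junction(idx[0] - 1, idx[0])
    j_out = junction(idx[-1], idx[-1] + 1)
    continuity_ok = all(
        j is not None and abs(j - JUNCTION_BOND) <= JUNCTION_TOL for j in (j_in, j_out)
    )

    loop_atoms = [a for i in idx for a in residues[i].atoms]
    # loop vs everything else, skipping the bonded neighbour residues
    neighbour_keys = set()
    for off in (idx[0] - 1, idx[-1] + 1):
        if 0 <= off < len(residues):
            neighbour_keys.add(residues[off].key)
    other_atoms = []
    for cid, chain_res in model.chains.items():
        for j, r in enumerate(chain_res):
            if cid == chain_id and idx[0] <= j <= idx[-1]:
                continue
            if r.key in neighbour_keys:
                continue
            other_atoms.extend(r.atoms)
    clash_count, _ = count_clashes(loop_atoms, other_atoms, scale=clash_scale)

    orientation_value: float | None = None
    orientation_ok = False
    if definition.lys_slot is not None and definition.lys_slot < n_loop:
        try:
            orientation_value, orientation_ok = orientation_feature(
                model, chain_id, residues[idx[0]].auth_seq_id, definition.lys_slot
            )
        except Exception:
            orientation_ok = False

    return GraftReport(
        loop_abego=loop_abego,
        pattern_retained=pattern_retained,
        junction_bond_lengths=(j_in, j_out),
        continuity_ok=continuity_ok,
        clash_count=clash_count,
        anchor_rmsd=0.0,
        orientation_value=orientation_value,
        orientation_ok=orientation_ok,
    )
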