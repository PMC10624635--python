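"""Backbone geometry: dihedrals, ABEGO torsion bins, superposition, and
internal-coordinate backbone construction.

Conventions
-----------
* Dihedral angles follow the IUPAC sign convention and live in (-180, 180].
* phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
  omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i) (the peptide bond *preceding*
  residue i).  Torsions are undefined at chain termini and across chain
  breaks, declared when the C(i)-N(i+1) distance exceeds 2.0 Å.
* ABEGO bins partition defined torsion space:
  O : omega defined and |omega| < 90 (cis peptide)
  A : phi < 0 and -75 <= psi < 50      (helical)
  B : phi < 0 and (psi >= 50 or psi < -75)  (extended)
  G : phi >= 0 and -100 <= psi < 100   (positive-phi turn)
  E : phi >= 0 and (psi >= 100 or psi < -100)
  '-': phi or psi undefined (termini, breaks, missing atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ploopkit.errors import GeometryError, SpecError
from ploopkit.structio import AtomRecord, ResidueRecord, StructureModel, AA3TO1

CHAIN_BREAK_CN = 2.0  # Å; peptide C-N is ~1.33 Å

# ideal internal coordinates (lengths in Å, angles in degrees) used by the
# sequential builder; only self-consistency with the torsion extractor matters
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


@dataclass(frozen=True)
class ResidueTorsions:
    """phi/psi/omega in degrees, ``None`` where undefined."""

    phi: float | None
    psi: float | None
    omega: float | None


@dataclass(frozen=True, eq=False)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _wrap_angle(deg: float) -> float:
    """Map an angle to (-180, 180]."""
    wrapped = math.remainder(deg, 360.0)
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees) of four points, IUPAC convention.

    angle = atan2((n1 x n2) . b2_hat, n1 . n2) with b1 = p2-p1, b2 = p3-p2,
    b3 = p4-p3, n1 = b1 x b2, n2 = b2 x b3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points in dihedral")
    b2_hat = b2 / np.linalg.norm(b2)
    angle = math.degrees(math.atan2(float(np.dot(np.cross(n1, n2), b2_hat)), float(np.dot(n1, n2))))
    return _wrap_angle(angle)


def _backbone(res: ResidueRecord) -> dict[str, np.ndarray] | None:
    coords = {}
    for name in ("N", "CA", "C"):
        atom = res.atom(name)
        if atom is None:
            return None
        coords[name] = atom.coords
    return coords


def backbone_torsions(chain: Sequence[ResidueRecord]) -> list[ResidueTorsions]:
    """Per-residue phi/psi/omega for a residue list in chain order.

    Residues lacking any of N/CA/C get fully undefined torsions, and break
    the chain for their neighbours, as does a C(i)-N(i+1) distance beyond
    the break threshold.
    """
    n = len(chain)
    bb = [_backbone(res) for res in chain]
    # linked[i]: residues i and i+1 are covalently continuous
    linked = [
        bb[i] is not None
        and bb[i + 1] is not None
        and float(np.linalg.norm(bb[i + 1]["N"] - bb[i]["C"])) <= CHAIN_BREAK_CN
        for i in range(n - 1)
    ]
    out: list[ResidueTorsions] = []
    for i in range(n):
        phi = psi = omega = None
        if bb[i] is not None:
            if i > 0 and linked[i - 1]:
                phi = dihedral_angle(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
                omega = dihedral_angle(bb[i - 1]["CA"], bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"])
            if i < n - 1 and linked[i]:
                psi = dihedral_angle(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
        out.append(ResidueTorsions(phi=phi, psi=psi, omega=omega))
    return out


def abego_classify(torsions: Sequence[ResidueTorsions]) -> str:
    """Map torsions to the ABEGO alphabet; '-' where phi or psi is undefined."""
    if len(torsions) == 0:
        raise SpecError("empty torsion list")
    chars = []
    for t in torsions:
        if t.omega is not None and abs(t.omega) < 90.0:
            chars.append("O")
        elif t.phi is None or t.psi is None:
            chars.append("-")
        elif t.phi < 0.0:
            chars.append("A" if -75.0 <= t.psi < 50.0 else "B")
        else:
            chars.append("G" if -100.0 <= t.psi < 100.0 else "E")
    return "".join(chars)


def abego_bin(phi: float, psi: float, omega: float = 180.0) -> str:
    """ABEGO character for explicit angles (degrees)."""
    return abego_classify([ResidueTorsions(phi=phi, psi=psi, omega=omega)])


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired points (reflections excluded).

    Returns the proper rotation R and translation t minimizing
    ||R·mobile + t - reference||; ``apply`` maps mobile coordinates onto the
    reference frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("superposition needs equal-length (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs >= 3 points, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # rank-deficient: all points collinear (or identical) -> rotation ambiguous
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom d bonded to c, with angle b-c-d and
    torsion a-b-c-d."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    rot = np.column_stack([bc_hat, m, n_hat])
    return c + rot @ d_local


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N, CA, C (tetrahedral construction).

    Used both by the backbone builder and to give Gly a virtual CB for the
    orientation feature.
    """
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_backbone(
    sequence: str,
    torsions: Sequence[tuple[float, float, float]],
    chain_id: str = "A",
    start_auth: int = 1,
    entry_id: str = "SYNTH",
) -> StructureModel:
    """Construct an ideal-geometry backbone from per-residue (phi, psi, omega).

    Atoms N/CA/C/O are placed for every residue and CB for every non-Gly
    residue by sequential internal-coordinate (NeRF) construction.  phi of
    the first residue and psi/omega entries that sequentially precede the
    chain are ignored; ``backbone_torsions`` of the result reproduces the
    interior angles to well under 1e-3 degrees.
    """
    if len(sequence) != len(torsions):
        raise SpecError("sequence and torsion list lengths differ")
    if len(sequence) == 0:
        raise SpecError("empty backbone specification")
    for i, (phi, psi, omega) in enumerate(torsions):
        for name, val in (("phi", phi), ("psi", psi), ("omega", omega)):
            if not (-180.0 < val <= 180.0):
                raise SpecError(f"residue {i + 1}: {name}={val} outside (-180, 180]")

    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed frame for residue 1
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        omega_i = torsions[i][2]
        phi_i = torsions[i][0]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega_i)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)

    residues: list[ResidueRecord] = []
    one_to_three = {v: k for k, v in AA3TO1.items()}
    for i, letter in enumerate(sequence):
        res_name = one_to_three.get(letter.upper(), "ALA")
        atoms = [
            AtomRecord("N", "N", N[i]),
            AtomRecord("CA", "C", CA[i]),
            AtomRecord("C", "C", C[i]),
        ]
        # carbonyl O in the peptide plane: torsion psi - 180 about N-CA-C
        o_pos = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                            _wrap_angle(torsions[i][1] - 180.0))
        atoms.append(AtomRecord("O", "O", o_pos))
        if res_name != "GLY":
            atoms.append(AtomRecord("CB", "C", virtual_cbeta(N[i], CA[i], C[i])))
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                auth_seq_id=start_auth + i,
                res_name=res_name,
                one_letter=AA3TO1.get(res_name, "X"),
                atoms=atoms,
            )
        )
    return StructureModel(entry_id=entry_id, chains={chain_id: residues})


def transform_model(model: StructureModel, rotation: np.ndarray,
                    translation: np.ndarray) -> StructureModel:
    """Deep-copied model with every atom mapped through x -> R x + t."""
    import copy

    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    out = copy.deepcopy(model)
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coords = rotation @ atom.coords + translation
    for res in out.ligands:
        for atom in res.atoms:
            atom.coords = rotation @ atom.coords + translation
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ca_coords_by_auth(model: StructureModel, chain_id: str) -> dict[int, np.ndarray]:
    out = {}
    for res in model.chain(chain_id):
        atom = res.atom("CA")
        if atom is not None and not res.insertion_code:
            out[res.auth_seq_id] = atom.coords
    return out


def _aligned_pairs_by_sequence(model_a: StructureModel, chain_a: str,
                               model_b: StructureModel, chain_b: str) -> list[tuple[int, int]]:
    """Author-number pairs of residues matched by global sequence alignment."""
    from Bio import Align
    from ploopkit.structio import extract_chain_sequence

    seq_a, map_a = extract_chain_sequence(model_a, chain_a)
    seq_b, map_b = extract_chain_sequence(model_b, chain_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            pairs.append((map_a[a_start + off + 1], map_b[b_start + off + 1]))
    return pairs


def compare_models(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str = "A",
    chain_b: str = "A",
    pairing: str = "auth_number",
) -> SuperpositionResult:
    """Cα RMSD between two models after optimal superposition.

    Residues are paired by shared author number (default) or by global
    sequence alignment (``pairing="sequence_align"``), then superposed with
    the Kabsch algorithm.
    """
    ca_a = _ca_coords_by_auth(model_a, chain_a)
    ca_b = _ca_coords_by_auth(model_b, chain_b)
    if pairing == "auth_number":
        shared = sorted(set(ca_a) & set(ca_b))
        pairs = [(num, num) for num in shared]
    elif pairing == "sequence_align":
        pairs = [(a, b) for a, b in _aligned_pairs_by_sequence(model_a, chain_a, model_b, chain_b)
                 if a in ca_a and b in ca_b]
    else:
        raise SpecError(f"unknown pairing mode {pairing!r}")
    if len(pairs) < 3:
        raise GeometryError(f"only {len(pairs)} Cα pairs; need >= 3")
    mobile = np.array([ca_a[a] for a, _ in pairs])
    reference = np.array([ca_b[b] for _, b in pairs])
    return kabsch_superpose(mobile, reference)
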