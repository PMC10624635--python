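"""Seeded synthetic structures with known ground truth.

Fixtures emulate the native P-loop context — a β-strand entering the loop,
the eight-residue Walker-A segment with the EBBGAGAA torsion pattern, and an
exiting α-helix — built from ideal internal coordinates, so every detection,
grafting and constraint-evaluation operation can be exercised without any
external structure file.  All randomness (torsion jitter within a bin,
direction draws) goes through one NumPy PCG64 generator seeded explicitly,
so a given spec and seed reproduce bit-identical coordinates on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ploopkit.errors import FeasibilityError, SpecError
from ploopkit.geometry import build_backbone
from ploopkit.ligandfit import DistanceConstraint, LigandPose, evaluate_constraints
from ploopkit.structio import AtomRecord, ResidueRecord, StructureModel

#: representative (phi, psi, omega) inside each ABEGO bin; jitter of up to
#: ~10 degrees keeps every representative inside its bin
ABEGO_REPRESENTATIVE = {
    "A": (-57.0, -47.0, 180.0),
    "B": (-120.0, 130.0, 180.0),
    "G": (60.0, 40.0, 180.0),
    "E": (60.0, 170.0, 180.0),
    "O": (-75.0, 160.0, 10.0),
}

#: residue alphabet for filler segments; contains no Gly or Lys, so filler
#: can never complete a Walker-A sequence match
_FILLER_ALPHABET = "AVLIEDNQRFM"

#: a pre-loop (phi, psi, omega) that flips the orientation feature: with the
#: residue immediately before the motif in this conformation, its CB points
#: *toward* the conserved Lys (positive cosine), while the motif window
#: itself keeps its torsion pattern.  Frozen after a numerical scan over the
#: pre-residue torsion space of the default fixture.
ORIENTATION_FAIL_PRE_TORSION = (-150.0, -50.0, 180.0)

DEFAULT_SEGMENTS = (("strand", 6), ("motif", "GPPGAGKS", "EBBGAGAA"), ("helix", 8))


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative synthetic-backbone recipe.

    ``segments`` is a tuple of ``("helix", n)``, ``("strand", n)``,
    ``("motif", sequence, abego)`` or ``("explicit", sequence, torsions)``
    entries.  ``pre_loop_override`` forces the (phi, psi, omega) of the
    residue immediately before the first motif segment, used to build
    orientation-negative fixtures.
    """

    segments: tuple = DEFAULT_SEGMENTS
    seed: int = 0
    chain_id: str = "A"
    start_auth: int = 1
    jitter_deg: float = 5.0
    pre_loop_override: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise SpecError("seed must be a non-negative integer")
        for seg in self.segments:
            if seg[0] not in {"helix", "strand", "motif", "explicit"}:
                raise SpecError(f"unknown segment preset {seg[0]!r}")
            if seg[0] == "motif" and len(seg[1]) != len(seg[2]):
                raise SpecError("motif sequence and ABEGO string lengths differ")


@dataclass
class FixtureTruth:
    """Ground truth recorded while a fixture is built."""

    sequence: str
    torsions: list[tuple[float, float, float]]
    motif_starts_auth: list[int]
    motif_abego: dict[int, str] = field(default_factory=dict)
    motif_sequences: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "motif_starts_auth": self.motif_starts_auth,
            "motif_abego": self.motif_abego,
            "motif_sequences": self.motif_sequences,
        }


def _jitter(rng: np.random.Generator, angles: tuple[float, float, float],
            amplitude: float) -> tuple[float, float, float]:
    phi, psi, omega = angles
    d = rng.uniform(-amplitude, amplitude, size=2)
    return (phi + d[0], psi + d[1], omega)


def make_motif_fixture(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    """Build a synthetic backbone from segment presets, with ground truth.

    Motif segments record their expected hit start (author number) and
    ABEGO string; torsion jitter is drawn per residue but bounded so every
    residue stays inside its intended bin.
    """
    rng = np.random.default_rng(spec.seed)
    amplitude = min(spec.jitter_deg, 9.0)
    sequence_parts: list[str] = []
    torsions: list[tuple[float, float, float]] = []
    motif_starts: list[int] = []
    motif_abego: dict[int, str] = {}
    motif_sequences: dict[int, str] = {}
    offset = 0
    first_motif_pre_index: int | None = None
    for seg in spec.segments:
        kind = seg[0]
        if kind in {"helix", "strand"}:
            n = int(seg[1])
            char = "A" if kind == "helix" else "B"
            seq = "".join(rng.choice(list(_FILLER_ALPHABET), size=n))
            sequence_parts.append(seq)
            torsions.extend(
                _jitter(rng, ABEGO_REPRESENTATIVE[char], amplitude) for _ in range(n)
            )
            offset += n
        elif kind == "motif":
            _, seq, abego = seg
            start_auth = spec.start_auth + offset
            motif_starts.append(start_auth)
            motif_abego[start_auth] = abego
            motif_sequences[start_auth] = seq
            if first_motif_pre_index is None and offset > 0:
                first_motif_pre_index = offset - 1
            sequence_parts.append(seq)
            torsions.extend(
                _jitter(rng, ABEGO_REPRESENTATIVE[char], amplitude) for char in abego
            )
            offset += len(seq)
        else:  # explicit
            _, seq, explicit = seg
            sequence_parts.append(seq)
            torsions.extend(tuple(t) for t in explicit)
            offset += len(seq)
    if spec.pre_loop_override is not None:
        if first_motif_pre_index is None:
            raise SpecError("pre_loop_override needs a motif segment with a preceding residue")
        torsions[first_motif_pre_index] = tuple(spec.pre_loop_override)
    sequence = "".join(sequence_parts)
    model = build_backbone(
        sequence,
        torsions,
        chain_id=spec.chain_id,
        start_auth=spec.start_auth,
        entry_id=f"SYN{spec.seed}",
    )
    truth = FixtureTruth(
        sequence=sequence,
        torsions=torsions,
        motif_starts_auth=motif_starts,
        motif_abego=motif_abego,
        motif_sequences=motif_sequences,
    )
    return model, truth


def synthetic_designed_sequence(
    motif_start: int = 151,
    length: int = 440,
    seed: int = 2023,
) -> str:
    """Synthetic stand-in sequence for a designed nucleotide-binding subunit.

    One-letter sequence of ``length`` residues whose only Walker-A match is
    the designed loop ``GPPGAGKS`` placed so it starts at 1-based position
    ``motif_start`` (author numbering starting at 1).  Filler positions are
    drawn from an alphabet without Gly or Lys, so no spurious motif can
    arise.  This is a synthetic construction, not a deposited sequence.
    """
    loop = "GPPGAGKS"
    if motif_start < 1 or motif_start + len(loop) - 1 > length:
        raise SpecError("motif does not fit inside the requested sequence length")
    rng = np.random.default_rng(seed)
    filler = rng.choice(list(_FILLER_ALPHABET), size=length - len(loop))
    head = "".join(filler[: motif_start - 1])
    tail = "".join(filler[motif_start - 1 :])
    return head + loop + tail


def synthetic_donor_subunit(seed: int = 0, chain_id: str = "B",
                            motif_start_auth: int = 232) -> tuple[StructureModel, FixtureTruth]:
    """Synthetic stand-in for a P-loop donor subunit chain.

    A strand->P-loop->helix backbone, embedded in extra secondary structure,
    with the Walker-A loop placed so its first residue carries author number
    ``motif_start_auth`` (232 by default, the donor loop numbering).  This
    is a synthetic construction, not a deposited structure.
    """
    segments = (
        ("helix", 8),
        ("strand", 6),
        ("motif", "GPPGAGKS", "EBBGAGAA"),
        ("helix", 10),
        ("strand", 4),
    )
    start_auth = motif_start_auth - 14  # helix + strand precede the loop
    return make_motif_fixture(
        FixtureSpec(segments=segments, seed=seed, chain_id=chain_id, start_auth=start_auth)
    )


def perturb_model(model: StructureModel, noise_sd: float = 0.3,
                  seed: int = 0) -> StructureModel:
    """Deep copy with per-atom Gaussian coordinate noise plus a random rigid
    transform — a controllable stand-in for an independently solved copy of
    the same structure."""
    import copy as _copy

    from ploopkit.geometry import random_rotation

    rng = np.random.default_rng(seed)
    out = _copy.deepcopy(model)
    rot = random_rotation(rng)
    shift = rng.normal(scale=15.0, size=3)
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                noisy = atom.coords + rng.normal(scale=noise_sd, size=3)
                atom.coords = rot @ noisy + shift
    return out


def attach_phosphate(
    model: StructureModel,
    chain_id: str,
    auth_seq_id: int,
    atom_name: str,
    distance: float,
    seed: int = 0,
    label: str = "PB",
    res_name: str = "ATP",
    toward: tuple[str, int, str] | None = None,
) -> AtomRecord:
    """Append a single-phosphorus pseudo-ligand at an exact distance from a
    protein atom; returns the placed atom.

    The direction is a seeded random draw, or — when ``toward`` names
    another protein atom — the unit vector from the anchor to that atom,
    which keeps the phosphate inside the loop's grip.
    """
    anchor = model.find_residue(chain_id, auth_seq_id).atom(atom_name)
    if anchor is None:
        raise SpecError(f"no atom {atom_name} on {chain_id}/{auth_seq_id}")
    if toward is not None:
        target = model.find_residue(toward[0], toward[1]).atom(toward[2])
        if target is None:
            raise SpecError(f"no atom {toward[2]} on {toward[0]}/{toward[1]}")
        direction = target.coords - anchor.coords
    else:
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
    direction = direction / np.linalg.norm(direction)
    atom = AtomRecord(label, "P", anchor.coords + distance * direction, is_hetero=True)
    model.ligands.append(
        ResidueRecord(
            chain_id=chain_id,
            auth_seq_id=900 + len(model.ligands),
            res_name=res_name,
            atoms=[atom],
        )
    )
    return atom


def make_ligand_fixture(
    model: StructureModel,
    constraints: Sequence[DistanceConstraint],
    mode: str = "satisfy",
    margin: float = 0.5,
    seed: int = 0,
    res_name: str = "ATP",
) -> LigandPose:
    """Place phosphorus atoms that satisfy (or controllably violate) a
    constraint set.

    ``satisfy``: every constraint ends inside its flat-bottom band (zero
    penalty).  ``violate``: the *first* constraint is violated by exactly
    ``margin`` beyond its tolerance band, the rest stay satisfied; the
    designated constraint's ligand atom must not be shared with other
    constraints, otherwise the placement is refused.
    """
    if mode not in {"satisfy", "violate"}:
        raise SpecError(f"unknown ligand fixture mode {mode!r}")
    if not constraints:
        raise FeasibilityError("cannot build a ligand fixture from an empty constraint set")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[DistanceConstraint]] = {}
    for c in constraints:
        by_label.setdefault(c.ligand_atom, []).append(c)

    designated = constraints[0] if mode == "violate" else None
    if designated is not None and len(by_label[designated.ligand_atom]) > 1:
        raise FeasibilityError(
            "designated constraint shares its ligand atom with other constraints; "
            "cannot violate exactly one"
        )

    atoms: list[AtomRecord] = []
    for label, group in by_label.items():
        anchors = np.array([c.resolve_protein_atom(model) for c in group])
        targets = np.array([c.target for c in group])
        if designated is not None and label == designated.ligand_atom:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = anchors[0] + (designated.target + designated.tolerance + margin) * direction
        elif len(group) == 1:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = anchors[0] + targets[0] * direction
        else:
            x0 = anchors.mean(axis=0) + rng.normal(scale=0.5, size=3)
            best = None
            for _ in range(20):
                sol = least_squares(
                    lambda x: np.linalg.norm(x - anchors, axis=1) - targets, x0
                )
                if sol.cost < 1e-12:
                    best = sol.x
                    break
                x0 = anchors.mean(axis=0) + rng.normal(scale=2.0, size=3)
            if best is None:
                raise FeasibilityError(
                    f"no position satisfies all constraints on ligand atom {label!r}"
                )
            pos = best
        atoms.append(AtomRecord(label, "P", pos, is_hetero=True))

    pose = LigandPose(
        res_name=res_name,
        atoms=atoms,
        pose_id=f"fixture-{mode}-{seed}",
        provenance=f"sampled(seed={seed})",
    )
    report = evaluate_constraints(model, pose, constraints)
    if mode == "satisfy" and not report.all_satisfied:
        raise FeasibilityError("constraint set admits no satisfying placement")
    if mode == "violate":
        expected = [False] + [True] * (len(constraints) - 1)
        if report.satisfied != expected:
            raise FeasibilityError("could not violate exactly the designated constraint")
    return pose
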