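"""Nucleotide-pose evaluation against P-loop distance constraints.

The binding-mode search of the original design protocol is reduced to its
geometric core: declarative flat-bottom distance restraints between P-loop
atoms and the phosphorus atoms of the nucleotide, a hard-sphere clash count,
a seeded rigid-template sampler that proposes constraint-satisfying
phosphate poses, and the final candidate filter (torsion-pattern retention
plus a strict binding-score threshold, default < -8.0; the binding score
itself is an externally supplied number, e.g. a Rosetta ddG value — this
package never computes one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ploopkit.errors import AtomError, RadiusError, SpecError
from ploopkit.structio import AtomRecord, ResidueRecord, StructureModel

#: Bondi-style van der Waals radii (Å) for heavy atoms
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "MN": 1.73, "ZN": 1.39, "FE": 1.73, "NA": 2.27, "K": 2.75,
}

#: fraction of the radius sum below which a heavy-atom pair counts as a clash;
#: < 1 tolerates unminimized contact geometry
DEFAULT_CLASH_SCALE = 0.80

DEFAULT_SCORE_THRESHOLD = -8.0


@dataclass(frozen=True)
class DistanceConstraint:
    """Flat-bottom distance window between one protein atom and one ligand atom.

    Zero penalty while ``|d - target| <= tolerance``; outside the band the
    penalty grows as ``weight * (|d - target| - tolerance)**2``.
    """

    chain_id: str
    auth_seq_id: int
    atom_name: str
    ligand_atom: str  # e.g. PA, PB, PG
    target: float  # Å
    tolerance: float = 0.0  # Å
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise SpecError(f"constraint target must be positive, got {self.target}")
        if self.tolerance < 0 or self.weight < 0:
            raise SpecError("constraint tolerance and weight must be non-negative")

    def resolve_protein_atom(self, model: StructureModel) -> np.ndarray:
        res = model.find_residue(self.chain_id, self.auth_seq_id)
        atom = res.atom(self.atom_name)
        if atom is None:
            raise AtomError(
                f"constraint selector {self.chain_id}/{self.auth_seq_id}/{self.atom_name}: "
                "no such atom"
            )
        return atom.coords

    @property
    def protein_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_id, self.atom_name)


@dataclass
class LigandPose:
    """A placed nucleotide (or bare phosphate template)."""

    res_name: str
    atoms: list[AtomRecord]
    pose_id: str = "pose"
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        if not any(a.element == "P" for a in self.atoms):
            raise SpecError(f"pose {self.pose_id!r} has no phosphorus atom")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def as_residue(self, chain_id: str = "X", auth_seq_id: int = 900) -> ResidueRecord:
        return ResidueRecord(
            chain_id=chain_id,
            auth_seq_id=auth_seq_id,
            res_name=self.res_name,
            atoms=[
                AtomRecord(a.atom_name, a.element, a.coords.copy(), is_hetero=True)
                for a in self.atoms
            ],
        )


@dataclass
class ConstraintReport:
    distances: list[float]
    violations: list[float]
    satisfied: list[bool]
    penalty: float
    all_satisfied: bool

    def to_dict(self) -> dict:
        return {
            "distances": self.distances,
            "violations": self.violations,
            "satisfied": self.satisfied,
            "penalty": self.penalty,
            "all_satisfied": self.all_satisfied,
        }


@dataclass
class DesignCandidate:
    """A grafted/designed structure plus pose, score and filter inputs."""

    candidate_id: str
    binding_score: float
    pattern_retained: bool
    constraint_penalty: float = 0.0
    clash_count: int = 0
    model: StructureModel | None = None
    pose: LigandPose | None = None
    extras: dict = field(default_factory=dict)


def evaluate_constraints(
    model: StructureModel,
    pose: LigandPose,
    constraints: Sequence[DistanceConstraint],
) -> ConstraintReport:
    """Measure each constrained distance and accumulate the flat-bottom
    quadratic penalty."""
    distances: list[float] = []
    violations: list[float] = []
    satisfied: list[bool] = []
    penalty = 0.0
    for c in constraints:
        p_coord = c.resolve_protein_atom(model)
        lig_atom = pose.atom(c.ligand_atom)
        if lig_atom is None:
            raise AtomError(f"constraint ligand atom {c.ligand_atom!r} absent from pose")
        d = float(np.linalg.norm(p_coord - lig_atom.coords))
        violation = max(0.0, abs(d - c.target) - c.tolerance)
        distances.append(d)
        violations.append(violation)
        satisfied.append(violation == 0.0)
        penalty += c.weight * violation**2
    return ConstraintReport(
        distances=distances,
        violations=violations,
        satisfied=satisfied,
        penalty=penalty,
        all_satisfied=all(satisfied),
    )


def _radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise RadiusError(f"no van der Waals radius for element {element!r}") from None


def count_clashes(
    atoms_a: Sequence[AtomRecord],
    atoms_b: Sequence[AtomRecord],
    scale: float = DEFAULT_CLASH_SCALE,
) -> tuple[int, float]:
    """Hard-sphere clash count between two heavy-atom sets.

    A pair clashes when its distance is strictly below ``scale * (r_i + r_j)``;
    returns the count and the summed overlap deficit (Å).
    """
    if not atoms_a or not atoms_b:
        return 0, 0.0
    ra = np.array([_radius(a.element) for a in atoms_a])
    rb = np.array([_radius(b.element) for b in atoms_b])
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    dist = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    limit = scale * (ra[:, None] + rb[None, :])
    deficit = limit - dist
    mask = deficit > 0.0
    return int(np.count_nonzero(mask)), float(deficit[mask].sum())


def clash_score(
    model: StructureModel,
    pose: LigandPose,
    scale: float = DEFAULT_CLASH_SCALE,
    exclude_protein_atoms: Iterable[tuple[str, int, str]] = (),
) -> tuple[int, float]:
    """Protein-ligand clash count and overlap sum.

    ``exclude_protein_atoms`` lists (chain, auth_seq_id, atom_name) triples
    — typically the constrained Lys/Ser contact set — whose short contacts
    are intended and therefore not counted.
    """
    excluded = set(exclude_protein_atoms)
    protein_atoms = [
        atom
        for chain_id, residues in model.chains.items()
        for res in residues
        for atom in res.atoms
        if (chain_id, res.auth_seq_id, atom.atom_name) not in excluded
    ]
    return count_clashes(protein_atoms, pose.atoms, scale=scale)


#: rigid phosphate-chain templates: atom name -> coordinates (Å) in an
#: idealized local frame (P-P separation ~2.95 Å through bridging oxygens)
_TRIPHOSPHATE_TEMPLATE = {
    "PA": np.array([0.0, 0.0, 0.0]),
    "PB": np.array([2.95, 0.0, 0.0]),
    "PG": np.array([4.35, 2.55, 0.0]),
}
_DIPHOSPHATE_TEMPLATE = {k: _TRIPHOSPHATE_TEMPLATE[k] for k in ("PA", "PB")}


def sample_phosphate_poses(
    model: StructureModel,
    constraints: Sequence[DistanceConstraint],
    n: int = 10,
    seed: int = 0,
    res_name: str = "ATP",
    max_attempts: int = 200_000,
) -> list[LigandPose]:
    """Seeded rejection sampler for constraint-satisfying phosphate poses.

    A rigid tri- (or di-) phosphate template is placed by uniform random
    rotation; the translation is derived by putting the first constraint's
    ligand atom on a random point of that constraint's target sphere band,
    and the trial is kept only if every remaining constraint is satisfied
    too.  Deterministic for a fixed seed (NumPy PCG64 generator).  If the
    attempt budget runs out before ``n`` acceptances a feasibility warning
    is emitted and the accepted poses (possibly none) are returned.
    """
    labels = {c.ligand_atom for c in constraints}
    if len(labels) < 2:
        raise SpecError("pose sampling needs constraints on >= 2 distinct phosphorus labels")
    template = _TRIPHOSPHATE_TEMPLATE if "PG" in labels or res_name == "ATP" else _DIPHOSPHATE_TEMPLATE
    unknown = labels - set(template)
    if unknown:
        raise SpecError(f"constraints reference unknown phosphate labels: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    names = sorted(template)
    local = np.array([template[k] for k in names])
    local = local - local.mean(axis=0)
    ref = constraints[0]
    ref_anchor = ref.resolve_protein_atom(model)
    ref_index = names.index(ref.ligand_atom)

    poses: list[LigandPose] = []
    for attempt in range(max_attempts):
        if len(poses) >= n:
            break
        rot = Rotation.random(rng=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(max(ref.target - ref.tolerance, 0.0), ref.target + ref.tolerance)
        shift = ref_anchor + radius * direction - rot @ local[ref_index]
        placed = local @ rot.T + shift
        pose = LigandPose(
            res_name=res_name,
            atoms=[AtomRecord(name, "P", xyz, is_hetero=True) for name, xyz in zip(names, placed)],
            pose_id=f"sampled-{seed}-{len(poses)}",
            provenance=f"sampled(seed={seed})",
        )
        if evaluate_constraints(model, pose, constraints).all_satisfied:
            poses.append(pose)
    if len(poses) < n:
        warnings.warn(
            f"phosphate pose sampling: {len(poses)}/{n} poses accepted in "
            f"{max_attempts} attempts; constraint set may be infeasible",
            stacklevel=2,
        )
    return poses


def filter_candidates(
    candidates: Sequence[DesignCandidate],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    require_pattern: bool = True,
    max_penalty: float = 0.0,
) -> list[DesignCandidate]:
    """Apply the final design filter in stable input order.

    Retains candidates that kept the conserved torsion pattern (when
    required), whose binding score is strictly below the threshold, and
    whose constraint penalty does not exceed ``max_penalty``.
    """
    return [
        c
        for c in candidates
        if (c.pattern_retained or not require_pattern)
        and c.binding_score < score_threshold
        and c.constraint_penalty <= max_penalty
    ]


def constraints_from_survey(
    survey,
    model: StructureModel,
    hit,
    definition=None,
    min_tolerance: float = 0.25,
    weight: float = 1.0,
    probes: Sequence[str] | None = None,
) -> list[DistanceConstraint]:
    """Turn survey distance statistics into default constraints for one hit.

    Each (motif atom, phosphorus label) pair in the survey's distance table
    becomes a flat-bottom constraint on the corresponding atom of ``hit``
    with target = mean and tolerance = max(sd, ``min_tolerance``).
    Motif-atom labels are the survey's probe names: ``N@k`` (backbone N of
    motif position k), ``LYS_NZ`` and ``TS_OG``; ``probes`` restricts the
    emitted constraints to a subset of those labels.
    """
    from ploopkit.motif import MotifDefinition

    definition = definition or MotifDefinition.walker_a()
    residues = model.chain(hit.chain_id)
    start_idx = next(
        i for i, r in enumerate(residues) if r.auth_seq_id == hit.start_auth
    )

    def resolve_label(label: str) -> tuple[int, str] | None:
        if label.startswith("N@"):
            slot = int(label[2:]) - 1
            return residues[start_idx + slot].auth_seq_id, "N"
        if label == "LYS_NZ" and definition.lys_slot is not None:
            return residues[start_idx + definition.lys_slot].auth_seq_id, "NZ"
        if label == "TS_OG":
            res = residues[start_idx + definition.length - 1]
            og = res.atom("OG1") or res.atom("OG")
            return (res.auth_seq_id, og.atom_name) if og is not None else None
        return None

    constraints = []
    for row in survey.distance_summary().itertuples():
        if probes is not None and row.motif_atom not in probes:
            continue
        resolved = resolve_label(row.motif_atom)
        if resolved is None:
            continue
        auth_seq_id, atom_name = resolved
        res = model.find_residue(hit.chain_id, auth_seq_id)
        if res.atom(atom_name) is None:
            continue
        constraints.append(
            DistanceConstraint(
                chain_id=hit.chain_id,
                auth_seq_id=auth_seq_id,
                atom_name=atom_name,
                ligand_atom=str(row.ligand_atom),
                target=float(row.mean_A),
                tolerance=max(float(row.sd_A), min_tolerance),
                weight=weight,
            )
        )
    return constraints


def read_constraints_tsv(path: str | Path) -> list[DistanceConstraint]:
    """Load constraints from a TSV with columns chain, resid, atom,
    ligand_atom, target_A, tol_A, weight."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chain", "resid", "atom", "ligand_atom", "target_A", "tol_A", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise SpecError(f"constraints file missing columns: {sorted(missing)}")
    return [
        DistanceConstraint(
            chain_id=str(row.chain),
            auth_seq_id=int(row.resid),
            atom_name=str(row.atom),
            ligand_atom=str(row.ligand_atom),
            target=float(row.target_A),
            tolerance=float(row.tol_A),
            weight=float(row.weight),
        )
        for row in df.itertuples()
    ]


def read_candidates_tsv(path: str | Path) -> list[DesignCandidate]:
    """Load candidate rows (id, binding_score, pattern_retained and optional
    penalty/clash columns) from a TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"id", "binding_score"} <= set(df.columns):
        raise SpecError("candidates file needs at least 'id' and 'binding_score' columns")
    out = []
    for row in df.itertuples():
        retained = bool(getattr(row, "pattern_retained", True))
        if isinstance(getattr(row, "pattern_retained", True), str):
            retained = getattr(row, "pattern_retained").strip().lower() in {"1", "true", "t", "yes"}
        out.append(
            DesignCandidate(
                candidate_id=str(row.id),
                binding_score=float(row.binding_score),
                pattern_retained=retained,
                constraint_penalty=float(getattr(row, "penalty", 0.0)),
                clash_count=int(getattr(row, "clash_count", 0)),
            )
        )
    return out
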