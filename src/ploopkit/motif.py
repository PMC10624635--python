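"""Walker-A P-loop detection and survey statistics.

A P-loop (Walker-A motif, G-X1-X2-X3-X4-G-K-[T/S]) is recognized here by the
three features conserved across native nucleotide-binding loops:

1. **Sequence** — the fixed motif positions, plus an additional conserved
   Gly at the X3 wildcard slot by default.
2. **Backbone torsion pattern** — the ABEGO string over the motif residues
   must read ``EBBGAGAA`` (strand exit, two extended residues, the
   characteristic positive-phi kink, then the helical approach).
3. **Orientation** — the vector from the Cα of the last strand residue
   immediately before the loop to the Cα of the conserved Lys must point
   away from that residue's Cα→Cβ vector (negative cosine).

``detect_ploops`` applies all three to a structure; ``survey_motifs``
aggregates per-position residue and torsion-bin frequencies and
loop-to-phosphate distances over a structure set, from which default
distance constraints for ligand placement can be derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ploopkit.errors import AtomError, EmptyModelError, PloopkitError, SpecError
from ploopkit.geometry import (
    ResidueTorsions,
    abego_classify,
    backbone_torsions,
    virtual_cbeta,
)
from ploopkit.structio import ResidueRecord, StructureModel, extract_chain_sequence

#: default nucleotide residue names considered when collecting
#: loop-to-phosphate distances
DEFAULT_LIGAND_NAMES = frozenset({"ATP", "ADP", "ANP", "AGS", "ACP"})

#: a selected ligand counts as bound when one of its phosphorus atoms lies
#: within this distance of the motif's conserved-Lys Cα
LIGAND_PROXIMITY_CUTOFF = 10.0  # Å


@dataclass(frozen=True)
class MotifDefinition:
    """Walker-A motif expression: fixed slots, wildcards and torsion pattern.

    ``slots`` holds, per motif position, either ``None`` (wildcard) or the
    set of allowed one-letter codes.  ``'X'`` in a sequence never matches a
    fixed slot.  The default is G-X1-X2-X3-X4-G-K-[T/S] with the conserved
    Gly required at X3 and the torsion pattern EBBGAGAA.
    """

    slots: tuple[frozenset[str] | None, ...]
    torsion_pattern: str = "EBBGAGAA"
    orientation_required: bool = True
    lys_slot: int | None = 6  # 0-based index of the conserved Lys slot
    torsion_tolerance_deg: float | None = None  # None = exact character match

    def __post_init__(self) -> None:
        if len(self.torsion_pattern) != len(self.slots):
            raise SpecError("torsion pattern length differs from sequence pattern length")
        if self.lys_slot is not None and not 0 <= self.lys_slot < len(self.slots):
            raise SpecError("conserved-Lys slot outside the motif")

    @property
    def length(self) -> int:
        return len(self.slots)

    @classmethod
    def walker_a(
        cls,
        require_x3_gly: bool = True,
        include_lys: bool = True,
        torsion_pattern: str = "EBBGAGAA",
        orientation_required: bool = True,
        torsion_tolerance_deg: float | None = None,
    ) -> "MotifDefinition":
        """The canonical motif; ``include_lys=False`` gives the shorter
        G-X1-X2-X3-X4-G-[T/S] variant (one fewer slot)."""
        g = frozenset("G")
        kt = frozenset("TS")
        x3 = g if require_x3_gly else None
        if include_lys:
            slots = (g, None, None, x3, None, g, frozenset("K"), kt)
            lys_slot = 6
            pattern = torsion_pattern
        else:
            slots = (g, None, None, x3, None, g, kt)
            lys_slot = None
            pattern = torsion_pattern[: len(slots)]
        return cls(
            slots=slots,
            torsion_pattern=pattern,
            orientation_required=orientation_required and include_lys,
            lys_slot=lys_slot,
            torsion_tolerance_deg=torsion_tolerance_deg,
        )

    def with_tolerance(self, degrees: float | None) -> "MotifDefinition":
        return replace(self, torsion_tolerance_deg=degrees)


@dataclass
class MotifHit:
    """One detected P-loop and its per-feature verdicts."""

    chain_id: str
    start_auth: int
    end_auth: int
    matched_sequence: str
    abego: str
    orientation_value: float | None
    sequence_ok: bool
    torsion_ok: bool
    orientation_ok: bool
    failure_reasons: list[str] = field(default_factory=list)
    start_index: int = 0  # 1-based index into the chain sequence

    @property
    def confirmed(self) -> bool:
        return self.sequence_ok and self.torsion_ok and self.orientation_ok

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "start_auth": self.start_auth,
            "end_auth": self.end_auth,
            "matched_sequence": self.matched_sequence,
            "abego": self.abego,
            "orientation_value": self.orientation_value,
            "sequence_ok": self.sequence_ok,
            "torsion_ok": self.torsion_ok,
            "orientation_ok": self.orientation_ok,
            "confirmed": self.confirmed,
            "failure_reasons": ";".join(self.failure_reasons),
        }


@dataclass
class MotifSurvey:
    """Aggregated statistics over confirmed hits in a structure set."""

    n_structures: int
    n_hits: int
    residue_frequencies: pd.DataFrame  # index: residue letter, columns: motif position (1-based)
    abego_frequencies: pd.DataFrame
    orientation_summary: dict[str, float]
    phosphate_distances: pd.DataFrame  # columns: motif_atom, ligand_atom, distance_A

    def modal_abego(self) -> str:
        return "".join(self.abego_frequencies[c].idxmax() for c in self.abego_frequencies.columns)

    def distance_summary(self) -> pd.DataFrame:
        """Mean/sd/count of each (motif atom, phosphorus) distance pair."""
        if self.phosphate_distances.empty:
            return pd.DataFrame(columns=["motif_atom", "ligand_atom", "mean_A", "sd_A", "n"])
        grouped = self.phosphate_distances.groupby(["motif_atom", "ligand_atom"])["distance_A"]
        out = grouped.agg(mean_A="mean", sd_A="std", n="count").reset_index()
        out["sd_A"] = out["sd_A"].fillna(0.0)
        return out


def scan_walker_a(sequence: str, definition: MotifDefinition | None = None) -> list[int]:
    """All (possibly overlapping) 1-based start indices matching the motif's
    fixed slots; wildcards are free. ``'X'`` never matches a fixed slot."""
    definition = definition or MotifDefinition.walker_a()
    seq = sequence.upper()
    length = definition.length
    starts = []
    for start in range(len(seq) - length + 1):
        window = seq[start : start + length]
        if all(allowed is None or window[j] in allowed
               for j, allowed in enumerate(definition.slots)):
            starts.append(start + 1)
    return starts


def _residue_cb(res: ResidueRecord) -> np.ndarray:
    cb = res.atom("CB")
    if cb is not None:
        return cb.coords
    needed = [res.atom(n) for n in ("N", "CA", "C")]
    if any(a is None for a in needed):
        raise AtomError(
            f"residue {res.chain_id}/{res.auth_seq_id}: cannot build virtual CB "
            "(incomplete backbone)"
        )
    return virtual_cbeta(*(a.coords for a in needed))


def orientation_feature(
    model: StructureModel,
    chain_id: str,
    start_auth: int,
    conserved_lys_slot: int,
) -> tuple[float, bool]:
    """Orientation of the conserved Lys relative to the pre-loop residue.

    With ``pre`` the residue immediately before the motif start in chain
    order, returns the cosine between the unit vectors Cα(pre)→Cα(Lys) and
    Cα(pre)→Cβ(pre) (virtual Cβ for Gly), and the ``points_away`` flag
    (cosine strictly negative).
    """
    residues = model.chain(chain_id)
    idx = next((i for i, r in enumerate(residues) if r.auth_seq_id == start_auth
                and not r.insertion_code), None)
    if idx is None:
        raise AtomError(f"no residue {start_auth} in chain {chain_id!r}")
    if idx == 0:
        raise PloopkitError(
            f"motif at {chain_id}/{start_auth} starts the chain: no preceding strand residue"
        )
    pre = residues[idx - 1]
    lys_idx = idx + conserved_lys_slot
    if lys_idx >= len(residues):
        raise AtomError("conserved-Lys slot extends past the chain end")
    lys = residues[lys_idx]
    ca_pre = pre.atom("CA")
    ca_lys = lys.atom("CA")
    if ca_pre is None or ca_lys is None:
        raise AtomError("missing CA atom for orientation feature")
    cb_pre = _residue_cb(pre)
    v1 = ca_lys.coords - ca_pre.coords
    v2 = cb_pre - ca_pre.coords
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise AtomError("degenerate orientation vectors")
    cosine = float(np.dot(v1 / n1, v2 / n2))
    return cosine, cosine < 0.0


# phi/psi intervals of each ABEGO bin on the periodic angle circle
# (intervals are [lo, hi) with hi > lo; width < 360 except where noted)
_BIN_BOUNDS = {
    "A": ((-180.0, 0.0), (-75.0, 50.0)),
    "B": ((-180.0, 0.0), (50.0, 285.0)),   # psi >= 50 or psi < -75 (wrapped)
    "G": ((0.0, 180.0), (-100.0, 100.0)),
    "E": ((0.0, 180.0), (100.0, 260.0)),   # psi >= 100 or psi < -100 (wrapped)
}


def _circular_distance_to_interval(x: float, lo: float, hi: float) -> float:
    """Angular distance (degrees) from x to the interval [lo, hi) on a circle."""
    offset = (x - lo) % 360.0
    width = (hi - lo) % 360.0 or 360.0
    if offset < width:
        return 0.0
    return min(offset - width, 360.0 - offset)


def _angle_to_bin(phi: float, psi: float, char: str) -> float:
    """Chebyshev distance (degrees) from (phi, psi) to the target bin."""
    (phi_lo, phi_hi), (psi_lo, psi_hi) = _BIN_BOUNDS[char]
    return max(
        _circular_distance_to_interval(phi, phi_lo, phi_hi),
        _circular_distance_to_interval(psi, psi_lo, psi_hi),
    )


def torsion_pattern_matches(
    abego: str,
    torsions: Sequence[ResidueTorsions],
    pattern: str,
    tolerance_deg: float | None = None,
) -> bool:
    """Exact per-character match by default; in tolerance mode a residue also
    matches when its (phi, psi) lies within ``tolerance_deg`` of the required
    bin.  '-' (undefined) never matches."""
    if len(abego) != len(pattern):
        return False
    for char, want, t in zip(abego, pattern, torsions):
        if char == want:
            continue
        if tolerance_deg is None or char == "-" or want not in _BIN_BOUNDS:
            return False
        if t.phi is None or t.psi is None:
            return False
        if _angle_to_bin(t.phi, t.psi, want) > tolerance_deg:
            return False
    return True


def detect_ploops(
    model: StructureModel,
    definition: MotifDefinition | None = None,
) -> list[MotifHit]:
    """Scan every chain for Walker-A motifs and evaluate all three conserved
    features at each sequence match.

    Unscoreable criteria (chain-terminal motif, missing atoms) are recorded
    as failed with a reason rather than raised.
    """
    definition = definition or MotifDefinition.walker_a()
    model.require_polymer()
    hits: list[MotifHit] = []
    for chain_id, residues in model.chains.items():
        if len(residues) < definition.length:
            continue
        sequence, mapping = extract_chain_sequence(model, chain_id)
        torsions = backbone_torsions(residues)
        abego_full = abego_classify(torsions)
        for start in scan_walker_a(sequence, definition):
            i0 = start - 1
            window_abego = abego_full[i0 : i0 + definition.length]
            window_torsions = torsions[i0 : i0 + definition.length]
            reasons: list[str] = []
            torsion_ok = torsion_pattern_matches(
                window_abego,
                window_torsions,
                definition.torsion_pattern,
                definition.torsion_tolerance_deg,
            )
            if not torsion_ok:
                reasons.append(f"torsion pattern {window_abego} != {definition.torsion_pattern}")
            orientation_value: float | None = None
            if definition.orientation_required and definition.lys_slot is not None:
                try:
                    orientation_value, points_away = orientation_feature(
                        model, chain_id, mapping[start], definition.lys_slot
                    )
                    orientation_ok = points_away
                    if not points_away:
                        reasons.append(f"orientation cosine {orientation_value:+.3f} not negative")
                except PloopkitError as exc:
                    orientation_ok = False
                    reasons.append(f"orientation unscoreable: {exc}")
            else:
                orientation_ok = True
            hits.append(
                MotifHit(
                    chain_id=chain_id,
                    start_auth=mapping[start],
                    end_auth=mapping[start + definition.length - 1],
                    matched_sequence=sequence[i0 : i0 + definition.length],
                    abego=window_abego,
                    orientation_value=orientation_value,
                    sequence_ok=True,
                    torsion_ok=torsion_ok,
                    orientation_ok=orientation_ok,
                    failure_reasons=reasons,
                    start_index=start,
                )
            )
    return hits


def _hit_probe_atoms(model: StructureModel, hit: MotifHit,
                     definition: MotifDefinition) -> list[tuple[str, np.ndarray]]:
    """Atoms whose distances to ligand phosphorus atoms are surveyed:
    backbone N of every motif residue, Lys NZ, and Thr/Ser OG or OG1."""
    residues = model.chain(hit.chain_id)
    idx = next(i for i, r in enumerate(residues) if r.auth_seq_id == hit.start_auth)
    probes = []
    for slot in range(definition.length):
        res = residues[idx + slot]
        n_atom = res.atom("N")
        if n_atom is not None:
            probes.append((f"N@{slot + 1}", n_atom.coords))
        if definition.lys_slot is not None and slot == definition.lys_slot:
            nz = res.atom("NZ")
            if nz is not None:
                probes.append(("LYS_NZ", nz.coords))
        if slot == definition.length - 1 and res.res_name in {"THR", "SER"}:
            og = res.atom("OG1") or res.atom("OG")
            if og is not None:
                probes.append(("TS_OG", og.coords))
    return probes


def _lys_ca(model: StructureModel, hit: MotifHit, definition: MotifDefinition) -> np.ndarray | None:
    residues = model.chain(hit.chain_id)
    idx = next(i for i, r in enumerate(residues) if r.auth_seq_id == hit.start_auth)
    slot = definition.lys_slot if definition.lys_slot is not None else definition.length - 1
    atom = residues[idx + slot].atom("CA")
    return None if atom is None else atom.coords


def survey_motifs(
    models: Iterable[StructureModel],
    definition: MotifDefinition | None = None,
    ligand_names: frozenset[str] | set[str] = DEFAULT_LIGAND_NAMES,
) -> MotifSurvey:
    """Aggregate confirmed-hit statistics over a structure set.

    Per-position residue and ABEGO frequencies are computed over all
    confirmed hits.  For every model containing a selected ligand whose
    phosphorus atoms come within :data:`LIGAND_PROXIMITY_CUTOFF` of the
    hit's conserved-Lys Cα, distances from the motif probe atoms (backbone
    N per position, Lys NZ, Thr/Ser OG) to each ligand phosphorus are
    recorded; their means and standard deviations seed default distance
    constraints.
    """
    definition = definition or MotifDefinition.walker_a()
    models = list(models)
    residue_counts: list[dict[str, int]] = [dict() for _ in range(definition.length)]
    abego_counts: list[dict[str, int]] = [dict() for _ in range(definition.length)]
    orientation_values: list[float] = []
    distance_rows: list[dict] = []
    n_hits = 0
    for model in models:
        for hit in detect_ploops(model, definition):
            if not hit.confirmed:
                continue
            n_hits += 1
            for pos, (aa, bin_char) in enumerate(zip(hit.matched_sequence, hit.abego)):
                residue_counts[pos][aa] = residue_counts[pos].get(aa, 0) + 1
                abego_counts[pos][bin_char] = abego_counts[pos].get(bin_char, 0) + 1
            if hit.orientation_value is not None:
                orientation_values.append(hit.orientation_value)
            anchor = _lys_ca(model, hit, definition)
            if anchor is None:
                continue
            probes = _hit_probe_atoms(model, hit, definition)
            for lig in model.ligands:
                if lig.res_name not in ligand_names:
                    continue
                p_atoms = [a for a in lig.atoms if a.element == "P"]
                if not p_atoms:
                    continue
                if min(np.linalg.norm(a.coords - anchor) for a in p_atoms) > LIGAND_PROXIMITY_CUTOFF:
                    continue
                for p_atom in p_atoms:
                    for label, coords in probes:
                        distance_rows.append(
                            {
                                "motif_atom": label,
                                "ligand_atom": p_atom.atom_name,
                                "distance_A": float(np.linalg.norm(p_atom.coords - coords)),
                            }
                        )
    if n_hits == 0:
        raise EmptyModelError("survey found no confirmed P-loop hits")

    def to_frame(counts: list[dict[str, int]]) -> pd.DataFrame:
        letters = sorted({k for col in counts for k in col})
        data = {
            pos + 1: [counts[pos].get(letter, 0) / sum(counts[pos].values()) for letter in letters]
            for pos in range(len(counts))
        }
        return pd.DataFrame(data, index=letters)

    ori = np.array(orientation_values) if orientation_values else np.array([math.nan])
    return MotifSurvey(
        n_structures=len(models),
        n_hits=n_hits,
        residue_frequencies=to_frame(residue_counts),
        abego_frequencies=to_frame(abego_counts),
        orientation_summary={
            "mean": float(np.mean(ori)),
            "sd": float(np.std(ori, ddof=0)),
            "min": float(np.min(ori)),
            "max": float(np.max(ori)),
        },
        phosphate_distances=pd.DataFrame(
            distance_rows, columns=["motif_atom", "ligand_atom", "distance_A"]
        ),
    )
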