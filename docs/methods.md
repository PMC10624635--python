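# Methods

## Model of a P-loop and its three conserved features

The package treats a Walker-A P-loop as an eight-residue backbone segment
defined jointly by sequence, local backbone conformation, and one
site-level geometric relation.

**Sequence.** The motif expression is a slot list: fixed slots (G at
positions 1 and 6, K at 7, T or S at 8) and wildcards (X₁–X₄), with the
wildcard X₃ additionally fixed to Gly by default, reflecting its strong
conservation in functional P-loops. An `X` in a sequence (non-standard or
unknown residue) never satisfies a fixed slot. A shorter variant without
the conserved Lys (G-X₁-X₂-X₃-X₄-G-[T/S], 7 slots) is available for
surveys; the Lys-containing form is the default because the orientation
feature is defined through the conserved Lys.

**Backbone torsion pattern.** Backbone conformation is classified per
residue into ABEGO bins from (φ, ψ, ω):

| bin | condition | meaning |
|---|---|---|
| O | ω defined and \|ω\| < 90° | cis peptide |
| A | φ < 0 and −75 ≤ ψ < 50 | helical |
| B | φ < 0 and (ψ ≥ 50 or ψ < −75) | extended |
| G | φ ≥ 0 and −100 ≤ ψ < 100 | positive-φ turn |
| E | φ ≥ 0 otherwise | positive-φ extended |
| `-` | φ or ψ undefined | terminus / chain break / missing atoms |

Boundaries are inclusive on the lower edge; the four φ/ψ bins partition
defined torsion space exactly (property-tested on a 1° grid). The exact
numeric boundaries follow the convention of the backbone-design literature;
only the qualitative regions (helical, extended, positive-φ) are dictated
by the motif itself. The conserved loop pattern is `EBBGAGAA`: strand exit,
two extended residues, the positive-φ kink at the conserved X₃ Gly, then
the helical approach to the Lys.

Torsion-pattern matching is exact per character by default. A tolerance
mode accepts a residue whose (φ, ψ) lies within T degrees (Chebyshev
distance on the periodic torus, default 10°) of the required bin; this
exists because minimized or experimentally refined models can drift a few
degrees across a hard bin edge without changing conformation class. `-`
never matches.

**Orientation.** With `pre` the residue immediately before the motif start
in chain order, the feature is the cosine between unit vectors
Cα(pre)→Cα(Lys) and Cα(pre)→Cβ(pre); the criterion passes when the cosine
is strictly negative ("points away"). For Gly pre-residues a virtual Cβ is
constructed from N/CA/C by the standard ideal-geometry formula. Using the
chain-order predecessor rather than an independently assigned "last strand
residue" is a deliberate simplification: it is deterministic, requires no
secondary-structure assignment, and coincides with the strand-to-loop
architecture in which the motif occurs.

A hit is *confirmed* when all enabled criteria pass; failed criteria are
recorded with reasons rather than raised, so detection is total.

## Torsion conventions and geometry

Dihedrals use the IUPAC sign convention computed as
atan2((n₁×n₂)·b̂₂, n₁·n₂) with bond vectors b₁=p₂−p₁, b₂=p₃−p₂, b₃=p₄−p₃
and normals n₁=b₁×b₂, n₂=b₂×b₃; values live in (−180°, 180°]. φ(i) is
C(i−1)-N(i)-CA(i)-C(i), ψ(i) is N(i)-CA(i)-C(i)-N(i+1), and ω(i) is the
peptide torsion CA(i−1)-C(i−1)-N(i)-CA(i) preceding residue i. A chain
break is declared when C(i)–N(i+1) exceeds 2.0 Å (peptide bond ≈ 1.33 Å,
generous margin); torsions spanning a break are undefined.

Rigid superposition is the Kabsch algorithm (SVD with determinant
correction, reflections excluded); collinear or under-determined point sets
raise rather than return an arbitrary frame. Tests cross-check the RMSD
against direct numerical minimization over rotation vectors — an oracle
that shares no code with the SVD path.

The backbone builder places N/CA/C/O (+ Cβ for non-Gly) by sequential
internal-coordinate (NeRF) construction with fixed ideal values
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles
N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°, CA-C-O 120.8°). These values
matter only for self-consistency: building from a torsion spec and
re-measuring reproduces the spec to < 10⁻³ degrees (property-tested over
1,000 seeded draws), which is what fixture-based testing needs.

## Structure I/O conventions

Reading (PDB or mmCIF, gemmi-backed) keeps author numbering and insertion
codes, drops hydrogens and waters, routes non-water HETATM residues to a
ligand list, and collapses alternate locations to the highest-occupancy
conformer (ties broken toward the lexicographically first altloc) so all
downstream geometry sees a single conformer deterministically. MSE is kept
in the polymer and reads as `X` unless an alias table (e.g. MSE→M) is
supplied. Resolution is taken from the header when present
(`_refine.ls_d_res_high` / `_reflns.d_resolution_high` in mmCIF, REMARK 2
in PDB). Writing round-trips identities, numbering and coordinates to PDB
precision (10⁻³ Å).

## Surveys and derived distance constraints

`survey_motifs` aggregates confirmed hits over a structure set:
per-position residue and ABEGO frequencies (each column sums to 1 over
observed letters), orientation-cosine summary statistics, and
loop-to-phosphate distances. A ligand participates when it is a selected
nucleotide (ATP/ADP/analogues by default) with a phosphorus atom within
10 Å of the hit's conserved-Lys Cα — a generous, deterministic proximity
rule. Probe atoms are the backbone N of each motif position, Lys NZ, and
Thr/Ser OG(1); each probe-to-phosphorus distance is recorded and
summarized as mean ± sd.

These summaries seed default ligand restraints: target = mean,
tolerance = max(sd, 0.25 Å), as flat-bottom quadratics
penalty = Σ wᵢ·max(0, |dᵢ − d⁰ᵢ| − tolᵢ)². The flat-bottom quadratic is the
standard restraint shape when only a distance window, not a functional
form, is known; the tolerance floor prevents a small survey from producing
degenerate zero-width windows.

## Grafting

Grafting replaces the acceptor range's backbone (N, CA, C, O, plus Cβ)
with the donor range's atoms mapped through a rigid transform computed
from anchor Cα pairs. Two anchor modes are provided because the choice is
genuinely open:

- `flank_window(k)` (default, k = 4): the k residues on each side of the
  acceptor range paired with the corresponding donor flanks. Deterministic
  and local; requires no homology.
- `global_ca`: all Cα pairs matched by a global sequence alignment of the
  two chains — the whole-subunit superposition appropriate when donor and
  acceptor are homologous subunits.

The report records which mode was used, the anchor RMSD and pair count,
the recomputed loop ABEGO and whether it retains the expected pattern, the
C–N splice bond lengths at both junctions (continuity requires
1.33 ± 0.15 Å — peptide geometry with an engineering margin, since backbone
minimization is out of scope here), a hard-sphere clash count of the loop
against the rest of the structure, and the orientation feature of the new
loop. Grafted residues take the donor's sequence truncated at Cβ;
sequence design on the grafted backbone is outside this package. Atoms
outside the grafted range are never touched (bit-identity is
property-tested), and pre-transforming the donor by any rigid motion
changes nothing, since the anchor superposition factors it out.

## Clash model and pose sampling

A clash is a protein–ligand heavy-atom pair closer than
0.80·(rᵢ + rⱼ) using Bondi-style van der Waals radii; the 0.80 scale
tolerates unminimized contact geometry. Atoms named in the intended
contact set (e.g. the constrained Lys/Ser atoms) can be excluded. The
implementation is vectorized but must equal brute-force pair enumeration
exactly (tested).

The phosphate-pose sampler places a rigid 2–3-phosphorus template
(P–P ≈ 2.95 Å): each trial draws a uniform random rotation, puts the first
constraint's ligand atom on a uniformly drawn point of that constraint's
spherical tolerance band, derives the translation, and accepts the pose
only if *every* restraint is satisfied. All randomness flows through one
NumPy PCG64 generator with an explicit seed, so accepted poses are
bit-identical across runs and platforms. An exhausted attempt budget
yields a feasibility warning and however many poses were accepted —
contradictory restraint sets return zero poses rather than raising. This
sampler stands in for conformer-generator–driven placement; it explores
rigid phosphate geometry only, which is exactly the part the distance
restraints constrain.

## Candidate filtering

The final selection retains a candidate iff (i) its loop kept the
conserved torsion pattern (optional), (ii) its externally supplied binding
score is **strictly** below the threshold (default −8.0), and (iii) its
restraint penalty does not exceed the cap (default 0). Binding scores are
opaque numbers loaded from a table; the package deliberately computes no
physical binding energy, so the filter is exactly reproducible from its
inputs.

## Synthetic data: what it emulates and what it does not

The fixture engine builds strand(6) → Walker-A loop (GPPGAGKS, `EBBGAGAA`)
→ helix(8) backbones from ideal internal coordinates, with per-residue
torsion jitter (default ±5°, bounded so every residue stays inside its
intended bin) and filler sequences drawn from an alphabet without Gly/Lys
so no spurious motif can arise. Segment sizes mirror the native context
(a β-strand entering the loop, an α-helix leaving it). The default
construction was verified to satisfy the orientation criterion across
seeds (cosine ≈ −0.8); orientation-negative fixtures force a frozen
pre-loop torsion, found once by a numerical scan, that flips the Cβ
direction while leaving the loop pattern intact. Ligand fixtures place
phosphorus atoms to satisfy a restraint set exactly, or to violate exactly
one designated restraint by a stated margin.

Fixtures are idealized: exact bond lengths/angles, no side chains beyond
Cβ, no solvent, no packing environment, single chains. Tests passing on
them demonstrate the correctness of the geometric and combinatorial logic
— detection, classification, superposition, restraint arithmetic — not
robustness to experimental-structure pathologies (disorder, alternate
conformers beyond the altloc policy, missing atoms beyond the handled
cases, non-ideal geometry), for which real structures remain necessary.
The acceptance script's structure-level checks therefore run on these
synthetic stand-ins with the documented site numbering (loop at author
151–158, donor loop at 232–239 on chain B).

## Problem sizes and numerical choices

Default test and acceptance runs use chains of ~22–36 residues, panels of
20 positive + 14–21 negative fixtures, 8-structure surveys, 1,000-draw
round-trip sweeps and 100-point-set superposition cross-checks — sizes
chosen so the full suite exercises every code path in well under a minute
on one CPU. Ties and degenerate inputs are handled explicitly: boundary
clash distances do not count (strict inequality), an orientation cosine of
exactly 0 fails the strict "points away" test, zero-length or mismatched
graft ranges and collinear superposition inputs raise typed errors, and
unscoreable detection criteria are reported as failures with reasons.

## Known limitations

- No secondary-structure assignment: the "last strand residue" is the
  chain-order predecessor of the motif.
- No sequence design, side-chain packing, minimization or physical
  scoring; binding scores are external inputs.
- The pose sampler is rigid and phosphate-only; full nucleotide conformer
  exploration is out of scope.
- No symmetry/assembly expansion, density handling, Mg²⁺ coordination
  model, or topology-independent structure alignment; `compare_models`
  pairs residues by author number or sequence alignment, which can differ
  from subset-selecting aligners on divergent pairs.
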