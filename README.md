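# ploopkit

Toolkit for engineering nucleotide-binding sites at pseudo-active sites:
detecting Walker-A P-loops in protein structures, surveying their conserved
features, grafting a functional P-loop backbone onto a degenerate
(pseudo-)loop, and screening nucleotide placements and design candidates.

## The problem

Many protein complexes contain subunits whose active sites degenerated over
evolution into *pseudo-active sites* — for example the B subunit of the
V<sub>1</sub>-ATPase hexamer, which carries a "pseudo P-loop" where the
catalytic A subunit carries a true Walker-A P-loop. Restoring the lost
small-molecule-binding function of such a site is a route to building
allosteric control into the complex. The computational core of that
restoration is geometric: recognize what makes a functional P-loop, rebuild
one at the degenerate site, and check that candidate designs keep the
motif's signature while gripping the ligand's phosphates.

`ploopkit` implements that core. A P-loop is identified by three conserved
features:

1. **Sequence** — the Walker-A motif G-X₁-X₂-X₃-X₄-G-K-(T/S), with an
   additionally conserved Gly at X₃;
2. **Backbone torsion pattern** — the ABEGO string over the eight motif
   residues must read `EBBGAGAA`, where the bins partition (φ, ψ, ω) space
   (A: φ<0, −75≤ψ<50; B: φ<0, remainder; G: φ≥0, −100≤ψ<100; E: φ≥0,
   remainder; O: |ω|<90°);
3. **Orientation** — the vector Cα(pre-loop)→Cα(conserved Lys) must point
   away from the Cα→Cβ vector of the last strand residue before the loop
   (cosine < 0).

Around detection, the package provides: survey statistics (per-position
residue/torsion-bin frequencies, loop-to-phosphate distances) over structure
sets; rigid loop grafting with flank- or whole-chain Cα anchoring (Kabsch
superposition); flat-bottom distance restraints between P-loop atoms and
the phosphorus atoms of ATP/ADP with penalty Σ wᵢ·max(0, |dᵢ−d⁰ᵢ|−tolᵢ)²;
hard-sphere clash counting; a seeded sampler for restraint-satisfying
phosphate poses; and the final candidate filter (torsion pattern retained
AND externally supplied binding score < −8.0). Binding scores are opaque
inputs (e.g. Rosetta ddG values); the package never computes an energy.

A deterministic internal-coordinate backbone builder and fixture engine
generate synthetic strand→loop→helix structures with known ground truth, so
the whole pipeline runs and is tested without any structure download.

## Worked example

```python
from ploopkit import detect_ploops, read_structure
from ploopkit.fixtures import FixtureSpec, make_motif_fixture

model, truth = make_motif_fixture(FixtureSpec(seed=7))   # strand + P-loop + helix
hit = detect_ploops(model)[0]
print(hit.start_auth, hit.matched_sequence, hit.abego,
      round(hit.orientation_value, 3), hit.confirmed)
```

prints

```
7 GPPGAGKS EBBGAGAA -0.799 True
```

i.e. one Walker-A match starting at author residue 7, whose backbone
realizes the conserved `EBBGAGAA` torsion pattern and whose conserved Lys
lies on the far side of the pre-loop strand residue (cosine −0.799, the
"points away" criterion), so the hit is confirmed on all three features.

The same operations are available from the shell:

```
ploopkit fixtures --seed 7 --out-dir out
ploopkit detect --input out/fixture_seed7.pdb --out-dir out      # hits.tsv
ploopkit graft --donor donor.pdb --donor-chain B --donor-range 232-239 \
               --acceptor acceptor.pdb --acceptor-range 151-158 \
               --out grafted.pdb --report report.json
ploopkit filter --candidates candidates.tsv --score-threshold -8.0
```

All residue ranges are author-numbered and inclusive (e.g. the pseudo-loop
`151-158`, the donor loop `232-239`).

## Layout

- `ploopkit.structio` — PDB/mmCIF I/O (gemmi-backed), author numbering,
  altloc collapse, ligand routing
- `ploopkit.geometry` — dihedrals, ABEGO bins, Kabsch superposition,
  internal-coordinate backbone building, model comparison
- `ploopkit.motif` — Walker-A scanning, orientation feature, detection,
  surveys
- `ploopkit.graft` — loop transplantation and graft validation
- `ploopkit.ligandfit` — distance restraints, clash scoring, pose sampling,
  candidate filtering
- `ploopkit.fixtures` — seeded synthetic structures with ground truth
- `ploopkit.cli` — the `ploopkit` command

See `docs/methods.md` for the methods, parameter defaults and limitations.
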