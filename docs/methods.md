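# Methods

This note records the models, conventions and design choices behind
`colefuse`, in the spirit of a package's methods documentation: what each
stage computes, the assumptions it rests on, and what the synthetic
fixtures do and do not establish about real structures.

## Units and coordinate model

The internal length unit is the nanometre throughout; PDB I/O converts
to/from Ångströms by the exact factor 10. This keeps every published
constant the pipeline touches (restraint r₀ of 0.209/0.231 nm, force
constants in kJ mol⁻¹ nm⁻², H-bond cutoffs, clash cutoffs) on one scale
with no silent mixing.

Author residue numbering is preserved verbatim on read — NColE7 stays
446–576; nothing is renumbered. Reports that compare equivalent segments
across models (e.g. the 45-residue HNH motif) may relabel residues 1–n at
output time only (`rmsf_profile(..., renumber_from=1)`).

A `Structure` is chains → residues → atoms plus one or more congruent
coordinate frames; multi-MODEL PDB is the ensemble interchange format
(mmCIF and compressed trajectory formats are out of scope). Reading goes
through Biopython's strict parser; alternate locations keep altloc ' '/'A'
deterministically; coordinates survive a write/read round trip to the
format's 0.001 Å precision (the parser stores single-precision floats,
which is well inside that tolerance). Crystal structures carry no
hydrogens; every analysis that would need them has a heavy-atom fallback
(below).

## Chimera construction by DNA-window superposition

Two protein–DNA complexes are merged by rigid-body superposition of their
DNA over every pair of equal-length base-pair windows (defaults 5 and 8
bp), in both relative orientations. For duplexes of La and Lb pairs and
window w this enumerates 2·(La−w+1)·(Lb−w+1) candidates; both window
lengths are pooled and ranked jointly (the alternative — ranking them
separately — has no observable consequence since ranking is by score
alone).

* **Superposition atom set**: phosphate P and sugar C1′ of both strands in
  the window. These are present in essentially every crystallographic
  nucleotide and are insensitive to base identity; a missing atom in a
  windowed nucleotide is an error naming the residue, not a silent skip.
* **Antiparallel matching**: base pair i of window A meets base pair
  (w−1−i) of window B with the strands exchanged. Enumerating both
  orientations treats the duplex as the physically symmetric object it is.
* **Kabsch algorithm**: least-squares rotation via SVD with the
  determinant correction, so reflections are excluded (det = +1 always);
  collinear point sets raise a degeneracy error rather than returning an
  arbitrary rotation. The implementation is cross-checked in the test
  suite against an independently implemented quaternion (Horn) method to
  1e−9 nm on random instances.
* **Merging**: the donor complex is transformed onto the acceptor window,
  its DNA removed, and its protein chains renamed to avoid id collisions;
  the acceptor DNA — the zinc fingers' specific site — is the one kept.
* **Scoring**: candidate models are ranked by a steric clash score,
  Σ(cutoff−d)² over non-bonded pairs closer than the cutoff (strict `<`,
  default 0.25 nm; bonded = same or sequence-adjacent residue). A full
  force-field energy is deliberately not implemented; the scorer is a
  pluggable callable so one can be substituted. Ranking ties break by
  enumeration order, which makes the selection deterministic.
* **Clash relief** is steepest descent on that score with backtracking;
  the score is non-increasing over accepted steps and every mobile atom's
  total displacement is bounded by steps × step size, which is what makes
  the "non-linker atoms barely move" guarantee testable.

## Fusion composition algebra

NColE7 has 131 residues (446–576). A composition keeps X N-terminal and Y
C-terminal residues with X + Y < 131; reverse constructs (native order,
named NX–ZF–CY) and straight constructs (termini joined to the fingers,
named CY–ZF–NX) share the same bookkeeping. The invariant
X + Y + missing = 131 is enforced and property-tested.

Published tables of such models occasionally state a missing range that is
off by one from the (X, Y) arithmetic. The toolkit takes no side: the
primary constructor computes the range from (X, Y); an alternate
constructor (`FusionComposition.from_missing_range`) reproduces a stated
range verbatim. No silent reconciliation is attempted.

The inactivating-mutation screen ships as a packaged CSV (single, double,
triple and frameshift records; frameshifts carry no position and are
excluded from positional mapping). A site is "missing from a model" iff
its position lies in the model's gap; multi-site records report each
missing member. This reproduces the published per-model missing-site sets
(e.g. K525 single / E508 double for N46–ZF–C45).

The composite DNA builder prolongs the finger recognition site by a
repeat scheme — an ordered list of site slices and literal spacers. The
default site is the 11-mer GAACTATGAGG (the longest block common to both
construct sequences) and the default schemes reproduce the straight
18-mer GAACTATGAGGCAGAACT and reverse 23-mer AACTATGAGGCAGAACTATGAGG
exactly. Site and schemes are configuration, not code constants.

## Linker design

Fragment libraries come from in-silico digestion: every contiguous window
(length in a configurable range, default 3–12) of every protein chain
with complete N/Cα/C/O backbone becomes a fragment; runs are broken at
incomplete residues or where consecutive Cα–Cα distances leave
[0.2, 0.5] nm. A chain of L complete residues yields Σ_w (L−w+1)
fragments — the sliding-window closed form the tests verify.

A candidate linker for an anchor pair must (i) have a length in the
requested range, (ii) match the anchor gap: |Cα(first)–Cα(last) −
gap| ≤ dist_tol, and (iii) superpose its two terminal residues onto the
anchors within rmsd_max over the 8 backbone atoms. Both tolerances
default to 0.05 nm and are configurable; the end-to-end and anchor-RMSD
definitions use the backbone atom set the library stores. Results are
ranked by anchor RMSD with source-id tie-breaks, and the whole search
equals an exhaustive filter (tested against one on libraries of a few
hundred fragments).

Grafting inserts the fragment interior as polyalanine with an ideal Cβ
(standard tetrahedral reconstruction from N/Cα/C), fuses and renumbers
the chain contiguously, then applies clash relief with only linker atoms
mobile; a residual clash score above threshold is a graft failure, not a
warning. Side chains beyond Cβ are never built.

The position scan mutates each linker position to the 18 standard amino
acids other than cysteine (too reactive) and proline (its backbone
constraint is over-rewarded by simple stability estimates, and extra
prolines would rigidify the linker); those two never appear in scan
output. The scorer is a contract — (model, position, residue) → score,
lower better. The built-in reference scorer is steric: squared overlap of
a side-chain probe (per-residue radius proxy at the ideal Cβ) with the
surroundings. It is deterministic and monotone in side-chain bulk, which
is the property the tests pin; it is *not* a folding free energy, and no
claim is made that its absolute values mean anything.

## Simulation setup

Zn sites are restrained, not bonded: each Zn gets a harmonic distance
term to every His Nδ1/Nε2 or Cys Sγ within a capture radius (default
0.3 nm) — Zn–N(His) r₀ = 0.209 nm, k = 14 710 kJ mol⁻¹ nm⁻²; Zn–S(Cys)
r₀ = 0.231 nm, k = 18 150 kJ mol⁻¹ nm⁻². The functional form is the
GROMOS half-k convention E = ½k(r−r₀)², documented here because the
prefactor convention differs between codes; energies are zero only at r₀
and exactly quadratic, both property-tested.

Ion counts: neutralization adds |net charge| counter-ions of the
appropriate sign; the salt concentration then exchanges
round(c·N_water/55.345) waters per ion of each Na/Cl pair, 55.345 mol/L
being the molarity of pure water. Rounding is to the nearest integer
because the procedure is count-based. n_Na − n_Cl = −net_charge always.

The manifest records the target protocol (10 ns, 298 K, 1 atm, 0.2 M
NaCl, 0.9 nm solute–wall, 0.23 nm solute–solvent, compressibility
4.575×10⁻⁴ (kJ/mol/nm³)⁻¹, five 20 ps thermalization ramps + 20 ps at
298 K, SHAKE tolerance 10⁻⁴) as data, for provenance; the toolkit does
not run dynamics.

## Ensemble analysis

RMSD is least-squares-fitted per frame by default (rigid motion removed);
RMSF is the per-atom fluctuation about the ensemble mean after optional
fitting to frame 0, averaged within residues. Radius of gyration is
mass-weighted by default with a small element-mass table.

Hydrogen bonds: with explicit hydrogens, H···A ≤ 0.25 nm and D–H–A angle
≥ 135°; without (the crystal-structure case), donor–acceptor ≤ 0.35 nm.
Only polar heavy atoms (N, O, S, P) can participate regardless of the
selection, so carbon-only groups always count zero. The criterion is
configurable; the defaults follow common trajectory-analysis practice
since no single geometric definition is canonical.

The four catalytic observables are explicit-mapping driven: the user
names which residues of the analyzed model play R447, H545, V555 and
N560, plus the Zn and the scissile phosphate. Nothing is inferred from
sequence alignment — a wrong guess here would silently invalidate every
downstream number, so a missing atom is a hard mapping error naming the
role.

Interaction energies are plain pairwise sums (Coulomb with
f = 138.935 kJ mol⁻¹ nm e⁻², LJ C12/r¹² − C6/r⁶ with geometric-mean
combination), symmetric in group order, each unordered pair counted
once; an optional distance cutoff exists for parity experiments but no
reaction field or exclusion topology is applied. These are suitable for
comparing groups within one parameterization, not for reproducing
absolute published force-field energies — that would need the full
force field and the original 10-ns solvated trajectories, which is
explicitly out of scope. Block averaging (mean ± standard error over
block means) is provided for trajectory averages.

## Synthetic fixtures and what they show

The generators are pure functions of (spec, seed):

* **Ideal B-DNA** — reduced representation (P, C1′, glycosidic N per
  nucleotide) on a perfect helix, 0.34 nm rise / 36° twist. Because an
  ideal helix is invariant under its own screw transform, equal-length
  windows anywhere along it superpose exactly — which is what makes the
  window-superposition machinery testable against a zero. No sugar
  pucker, groove asymmetry or sequence dependence is modelled.
* **Toy complexes** — a smooth complete-backbone protein trace beside the
  helix plus Zn sites with ligand atoms placed at the coordination
  distances (His Nε2 at 0.209 nm, Cys Sγ at 0.231 nm) in tetrahedral
  directions, so restraint emission has a ground truth by construction.
* **Toy trajectories** — frame t = driftᵗ(base) + iid isotropic Gaussian
  noise. For that noise the per-atom RMSF has the closed form
  σ√(3(1−1/F)), the yardstick for the parameter-recovery tests.
  Correlated motion is deliberately not modelled.
* **Fragment libraries** — helical/extended backbone decoys with seeded
  placement and jitter (re-drawn if it would break chain continuity),
  plus a planting helper that copies the anchors into a fragment's
  termini; such a plant must return from the search at rank 1 with
  anchor RMSD ≈ 0.

Passing on these fixtures establishes the algebra and geometry of the
pipeline — enumeration counts, transform recovery, restraint parameters,
bookkeeping, statistics — on inputs with known ground truth. It does not
establish that any particular chimera is stable or active; that judgement
needs the real crystal-derived systems and solvated MD, which this
package prepares for but does not perform.

## Numerical choices and degenerate inputs

* Reflections are never accepted in superposition; collinear inputs and
  fewer than three points raise typed errors.
* Clash counting uses strict `<` at the cutoff; an atom pair exactly at
  the cutoff does not clash.
* Score ties (model selection, position scan) break deterministically —
  enumeration order and alphabetical residue name respectively.
* The empty selection, empty model list and empty fragment library are
  distinguished: operations whose result is naturally empty return empty
  (window enumeration with an oversized window, linker search over an
  empty library); operations that cannot proceed raise
  (`select_best_model([])`, fitting on < 3 atoms).
* Problem sizes in the test-suite and acceptance runs (≤ 500-fragment
  libraries, ≤ 500-frame toy trajectories, ≤ tens of residues) were
  chosen as the smallest sizes at which every closed form and recovery
  statistic is sharp; all scale linearly or quadratically if enlarged.

## Known limitations

* The clash score is a proxy; model ranking with it agrees with a
  force-field ranking only insofar as sterics dominate.
* Polyalanine grafting plus the radius-proxy scan cannot capture
  electrostatics or hydrogen bonding of designed linker side chains.
* The geometric H-bond fallback without hydrogens overcounts relative to
  an angle-aware criterion; flagged, not corrected.
* The B-DNA generator's reduced atom set cannot support minor-groove
  geometry analysis; tools needing full nucleotides must read real
  coordinates.
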