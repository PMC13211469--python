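# Methods

This note documents the models, conventions, numerical choices and known
limitations behind killerkit. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and cleavage convention

All residue coordinates are 1-based inclusive. A proteolytic site is
identified by its P1 residue: cleavage occurs **after** that residue, so
"cleaved after R44" is position 44 and the next segment starts at 45. This
matches how maturation sites are conventionally reported for killer toxins
and removes off-by-one ambiguity when comparing against domain diagrams.
The final residue of a sequence is never reported as a P1 site — cleavage
there releases nothing.

## Mass arithmetic

Average (not monoisotopic) residue masses are used, because secreted-toxin
masses are quoted in kilodaltons on the average-mass scale. The shipped
table (`data/residue_masses.json`, versioned) carries the standard average
residue masses; a peptide mass is the residue sum plus one water
(18.015 Da), minus 2.016 Da per disulfide bond (two hydrogens). The
disulfide correction is exact but invisible at 0.1 kDa print precision.
Under the strict alphabet policy any non-canonical letter is an error; the
lenient policy substitutes a mean residue mass of 110.0 Da for `X` with a
warning. Glycan masses are out of scope: glycosylation of protoxins is not
computable from sequence.

## Kex motif scanning and the curated boundary tables

The default dibasic motif set is {KR, RR}; KK/RK and monobasic-R candidate
sites are opt-in (`EXTENDED_POLICY`) because monobasic cleavage is less
common, though confirmed at some boundaries. Scanning reports every
occurrence, overlapping motifs included.

Curated per-toxin boundaries (`data/toxin_configs.json`) are **shipped data,
not derived**: the published per-toxin diagrams are not uniformly
reproducible from a single cleavage rule. For K1, for example, the printed
gamma domain starts at 148 although Kex2 cleaves after R149 (Kex1 then trims
the 148–149 dipeptide from alpha), and beta starts at 235 though cleavage is
after R233. We ship the printed values verbatim and keep
`propose_partition` (the pure cleavage rule: segment k ends at site k's P1)
as a separate, cross-checked artifact. `validate_partition` reconciles the
two with a ±2 residue slack and reports mismatches as findings, never
errors. Two special cases: K74 ships only its two established cleavage
positions (110, 220) because no full domain spans are printed for it; K62's
two domains (receptor-binding and aerolysin-core) are mapped onto the
restricted name set as delta and beta respectively.

Kex1 trimming is expressed as "remove N trailing residues from chain X"
(K1: N = 2 on alpha; K28: N = 1 on beta, exposing the HDEL motif). The
shipped mature-chain spans are post-trim.

## Signal-region heuristic

Dedicated signal-peptide predictors are out of scope, and the canonical
predictors are known to fail on toxins whose hydrophobic region is displaced
~30 residues from the N-terminus. The in-house heuristic therefore searches
for an h-region — a window of ≥ 8 residues with mean Kyte–Doolittle
hydropathy ≥ 1.6 — starting anywhere in the first 60 residues. Candidate
windows are ranked by mean hydropathy (rounded to 9 decimals so float noise
cannot split ties between subwindows of a homogeneous stretch), then length,
then position; overlapping windows are collapsed to one candidate per
hydrophobic stretch. The n-region (everything before the h-region) is
scored by its K/R count; cleavage candidates within 15 residues downstream
are scored by small residues (A/G/S/C) at the −1 and −3 positions. The
overall score is mean hydropathy + 0.5 × n-region positives + best cleavage
score. All thresholds are parameters. The output is a ranked candidate
list, never a hard call — an empty list is a legal result.

## Structure metrics

**Parsing.** PDB input is read through gemmi: model 1 and the first
alternate location by default, waters skipped, hydrogens retained but
flagged, per-residue confidence (pLDDT, 0–100) taken from the
temperature-factor column as AlphaFold-style models store it.

**Superposition.** Kabsch via SVD with determinant correction, so
reflections are always excluded; RMSD is the minimum over proper rigid
motions. Tests cross-check against an independent quaternion
(largest-eigenvalue) oracle to 1e-6 Å.

**Dihedrals.** IUPAC sign convention, angles in (−180, 180]. φ is undefined
for the first residue and ψ for the last; a C(i)–N(i+1) distance above
2.5 Å is a chain break and suppresses the angles across it; missing backbone
atoms suppress dependent angles with a logged warning.

**Ramachandran map.** A coarse rectangular region map
(`data/rama_map.json`) with separate sub-maps for general, glycine, proline
and pre-proline residues — a documented simplification of MolProbity-style
contours, sufficient for favored/allowed/outlier bookkeeping on ideal and
near-ideal geometry. The secondary-structure fraction (`ss_fraction`) is an
even coarser dihedral-bin surrogate for predictor-based assignment (helix:
φ ∈ [−100, −30], ψ ∈ [−80, −5]; strand: φ ∈ [−180, −45], ψ ∈ [90, 180] ∪
[−180, −150]); it is documented as such and should not be read as a
hydrogen-bond-based assignment.

**SASA.** Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points), probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80
/ P 1.80 Å, hydrogens excluded. No algorithm, probe or radius set is
canonical for the published burial figures, so these are stated conventions;
test tolerances (1% against the analytic sphere, 2% against the two-sphere
spherical-cap closed form, 0.5% rotational invariance) absorb method
differences, and an independent implementation (biotite, matched radii) is
cross-checked to 1%.

**Helix burial.** Isolated SASA of the span's atoms alone, minus the same
atoms' SASA inside the full model; percent buried is relative to the
isolated area, so it lies in [0, 100] and grows monotonically as occluders
are added. We quantify burial of the helix itself (not the pocket surface),
which is the interpretation consistent with percent-of-helix figures.

**Disulfides.** Purely geometric: CYS SG–SG pairs matched greedily by
ascending distance, each SG in at most one pair; ≤ 2.5 Å bonded, ≤ 3.0 Å
"near" (predicted models often leave real pairs slightly long). Both
cutoffs are parameters. No energetics.

**Amphipathicity.** Eisenberg consensus hydrophobicity scale; μH is the
magnitude of the vector sum of residue hydrophobicities placed at
100°/residue (an ideal helix). An 18-mer homopolymer completes exactly five
turns, so its μH is zero to machine precision — a closed-form oracle used in
the tests. Helical wheels use five residue classes (hydrophobic, positive,
negative, polar, aromatic); histidine is grouped as positive, cysteine and
glycine as hydrophobic — one defensible choice among several, fixed and
documented.

## Homolog-set analytics

The 75%/150% length filter uses **strict** inequalities — hits exactly at
the bounds are kept — reading "shorter than / longer than" literally; the
bounds are parameters. Percent shared across a group is
100 × |∩ all| / |∪ all| with the union of deduplicated hit ids as
denominator; published shared-percentage figures do not name a denominator,
so ours is stated explicitly. Family clustering is single-linkage on
overlap with permissive defaults (any nonzero overlap links), because toxin
families are grouped on qualitative overlap — two toxins can share only a
small fraction of a large union and still form one family. Taxon tallies
match lineage strings case-insensitively against a configurable keyword→
group map over the deduplicated union; unmatched hits are "unknown". ΔΔG
classification uses a symmetric band: > +2 kcal/mol destabilizing,
< −2 stabilizing, the closed interval between them stable.

## Synthetic generators

The generators define the study conditions for every self-contained test.
`gen_preprotoxin` defaults to a 316-residue preprotoxin with boundaries
after residues 44/149/233 and four cysteines — the canonical four-domain
layout at realistic scale. Filler residues exclude K, R and C, and all have
negative hydropathy, so the planted motifs, cysteines and h-region are
provably the only ones present (rejection of infeasible specs replaces
rejection sampling: with this alphabet no accidental feature can occur, and
specs whose features collide raise `InfeasibleSpec`). The h-region is a
homogeneous run of one hydrophobic letter so that the detection heuristic's
max-mean criterion recovers the planted span exactly. `gen_ideal_backbone`
builds N/CA/C chains by internal coordinates (NeRF chaining; N–CA 1.458,
CA–C 1.525, C–N 1.329 Å, standard angles, ω = 180°), making the input
(φ, ψ) the analytic ground truth; recovery is tested to 1e-3°. Sphere
scenes provide analytic SASA oracles; the occlusion scene surrounds a small
cluster with a shell dense enough (spacing 1 Å at radius 6 Å) that burial is
near-total by construction. `gen_hit_tables` plants families as shared hit-id
cores plus private ids, out-of-range hit lengths at 0.5× and 2× the query,
and a 96/2/2 fungal/bacterial/plant lineage split by default.

What the generators do **not** emulate: evolutionary sequence statistics,
predictor error modes in real structure models, glycosylation, E-values or
database-dependent hit counts. Passing the round-trip suite therefore shows
the pipeline is correct on inputs satisfying its assumptions; it does not
certify predictor-grade accuracy on real sequences, where the signal
heuristic in particular remains a ranked screen, not a validated predictor.

## Acceptance problem sizes

`scripts/acceptance.py` uses the same sizes as the worked examples: 960 SASA
points, 10–20-residue backbones, 10–20 random superposition/dihedral draws,
50-hit tables with 12 planted out-of-range lengths, and a three-member
overlap design of 141 shared + 1 private hit per query (97.9% shared). The
run completes in seconds. Quantities that require the real toxin sequences
(mature chain masses of specific toxins, their lengths, the K62 motif
position) are exercised by the acceptance tests only when
`data/toxin_preprotoxins.fasta` is supplied by the user, since those
sequences are database records not shipped with the package.

## Known limitations

* Curated boundaries inherit the internal inconsistencies of their printed
  sources (see the K1 discussion above); we do not reconcile them.
* The Ramachandran map is rectangular and coarse; borderline residues may
  classify differently than under MolProbity contours.
* Disulfide detection is geometric only and will miss pairs a model leaves
  longer than 3 Å apart.
* Published buried-area and RMSD figures for specific toxin models derive
  from coordinates not shipped here; the package reproduces the *methods*
  (with analytic and planted oracles), not those specific numbers.
* `ss_fraction` is a dihedral-bin surrogate, not a hydrogen-bond-based
  secondary-structure assignment.
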