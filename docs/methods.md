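# Methods

## Scientific setting

ApoE4 — the strongest genetic risk factor for late-onset Alzheimer's disease
— differs from the benign ApoE3 isoform by an Arg at position 112 that
propagates a long-range conformational change: the Trp34 indole sidechain
rotates from a "flip-in" orientation (perpendicular to the protein's long
axis, as in ApoE2/E3) to a "flip-out" orientation (parallel to the axis),
closing a small allosteric pocket. Structure correctors bind this pocket,
flip Trp34 back, and stabilize an ApoE3-like conformation. `apoescreen`
implements the *analytics* of a virtual screen for such correctors; the
docking, shape-overlay and MD engines themselves are out of scope and are
replaced by controlled synthetic generators.

## Consensus ranking

Each library compound is docked against a six-structure ensemble: two apo
ApoE3, two free (apo) ApoE4 and two stabilizer-bound (holo) ApoE4 crystal
structures. Because the free-ApoE4 pocket is closed by the flipped-out Trp34,
true binders dock *well* on holo structures and *poorly* on free structures
— docking ranks correlate with affinity positively on holo and negatively on
free structures. The consensus score exploits this contrast:

    consensus = mean(holo-ApoE4 rank) / mean(free-ApoE4 rank)

with per-structure ranks (1 = best docking score, average ties). Lower is
better; the score is invariant under uniform rescaling of ranks, strictly
increasing in each holo rank and decreasing in each free rank. Library
consensus ranks are assigned by ascending score with average ties.

On the bundled eight-compound benchmark (known stabilizers with NMR Kd from
0.5–900 µM), this ratio reproduces the published consensus ordering exactly,
and places the five sub-30-µM actives within the top 21/1258 ≈ 1.67 % of the
screened library.

### Rank/Kd correlation diagnostics

`correlation_diagnostics` correlates each structure's ranks, and the
consensus score, against Kd. The method is a parameter (`spearman` default —
ranks against affinities are ordinal data — plus `pearson` and `kendall`),
and the censoring policy is explicit: `substitute` (default; "<5" enters as
5), `midpoint` (bound/2 for upper bounds, 2×bound for lower), or `drop`.
"No binding" entries never enter numerically. On the benchmark, Pearson with
the non-binding 900 µM fragment excluded yields the free-ApoE4
anticorrelation (−0.55/−0.74) and a consensus/Kd correlation of 0.994; the
package treats this as one diagnostic among several, not a privileged
statistic.

### Enrichment

The enrichment factor at top-fraction *f* is (actives in top *f*)/(all
actives)/*f*; the top set is the floor of *f·N* best consensus ranks (at
least 1). Under random ranking its expectation is 1, which the test suite
verifies by seeded permutation (1000 draws, 3-standard-error band).

## Structure triage

Candidate receptor structures are filtered to non-mutant X-ray entries at
resolution ≤ 2 Å, then any structure whose observed Trp34 orientation
contradicts the expectation for its class (apo-E2/E3 flip-in, apo-E4
flip-out, holo-E4 flip-in) is removed with a reason. On the bundled
eight-structure metadata this removes exactly the two atypical entries
(1OR3, an ApoE3 caught flipped out; 1B68, an ApoE4 caught flipped in),
leaving two structures per category.

## Flip classification and trajectory observables

The protein's long axis is operationalized as the first principal axis of
the CA coordinates, sign-fixed toward increasing residue number. This is a
deliberate, isolated design choice (the axis is never formally defined in
the crystallographic literature); a helix-fit could be swapped in behind
`protein_axis` without touching callers. The Trp orientation vector runs
from CB to the centroid of the nine indole ring atoms — it tracks where the
sidechain points, which is what distinguishes the two states visually — and
the angle to the axis uses the absolute cosine, so it lies in [0, 90]° and
the axis sign is irrelevant. Flip-out iff angle ≤ 45°, the unique symmetric
boundary between "parallel" and "perpendicular". A χ-based nearest-center
classifier (`classify_flip_chi`) is provided as an alternative; the
axis-angle route is the default.

χ1 = N–CA–CB–CG and χ2 = CA–CB–CG–CD1 (CD1 fixes the branch, the standard
Trp convention). Dihedrals use the atan2 formulation with sign convention
*positive = clockwise looking down the central bond*; this is the mirror of
the right-hand-rule convention some libraries use (the unit tests pin the
convention against an independent implementation).

RMSD series superpose each frame's backbone onto frame 0 (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`), report that minimum as
backbone RMSD, and measure ligand RMSD after applying the *backbone*
transform without re-fitting — the usual convention for pocket-stability
analyses, since re-fitting the ligand would hide drift out of the pocket.

## Interaction detectors

Docked and crystal poses usually lack hydrogens, so hydrogen bonds use the
heavy-atom criterion: any interface N/O–N/O pair within 3.5 Å, annotated by
protein residue; donor/acceptor roles are not assigned. π-stacking covers
parallel stacking only (ring-centroid distance ≤ 5.5 Å, interplanar angle ≤
30° between least-squares plane normals); T-shaped contacts are out of
scope. Hydrophobic pocket occupancy counts ligand carbon/halogen atoms
within 4.5 Å of pocket-residue sidechain atoms (pocket residue list is a
parameter, default the Trp34 lining of the toy fixture) and labels the
connected ligand fragment with the most contacts; the record reports counts
and lets callers threshold, since no published minimum defines "filling".
Ligand connectivity and rings are perceived from distance-based bonds
(≤ 1.8 Å), exact for the toy ligands used here. All detectors are invariant
under rigid isometries and monotone in their cutoffs (property-tested).

A checklist record conjoins the corrector-defining criteria: Trp34 flip-in ∧
H-bond to Asp35 ∧ H-bond to Asp153 ∧ non-empty pocket fill. On the bundled
benchmark checklist, 8/8 known stabilizers are flip-in and 6/8 satisfy the
full conjunction (the two weakest each lack one Asp H-bond). Persistence
profiles are per-interaction means of per-frame indicators.

## Synthetic-data generators

### Docking screen (`gen_screen`)

Emulates the statistical structure of the benchmark screen, not its physics.
Latent activity is log10 Kd: actives log-uniform between the range low end
(1 µM) and the 30 µM activity cutoff; decoys log-uniform between 30 and
1000 µM — the active/decoy convention of screening benchmarks, where decoys
are presumed inactive. Coupling is a Gaussian copula: with activity z-score
*z*, a structure with coupling ρ scores

    score = −8.5 + 1.5·(ρ·z + √(1−ρ²)·ε) + noise_sd·η   (kcal/mol)

Defaults: holo coupling +0.95, free coupling −0.65 (the magnitudes the
benchmark ensemble exhibits), apoE3 columns at 0.8× the holo coupling,
noise_sd 0.25 kcal/mol. Kd below the 5 µM detection floor is emitted
censored ("<5"), exercising the censoring-aware parser. The generator also
emits two shape-similarity query tables (TanimotoCombo-like, clipped to
[0.05, 2], coupled to activity) so every pipeline stage has an input. What
the generator does **not** emulate: chemical series structure, score
non-Gaussianity, correlated errors between structures sharing a
conformation, or size/property biases between actives and decoys — passing
recovery tests therefore demonstrate correctness of the *analytics*, not
screening power on real libraries.

### Toy pose complex (`build_pose_complex`)

Built from idealized geometry (regular-polygon indole with 1.40 Å bonds,
standard backbone bond lengths), never from real coordinates: two backbone
segments along the x axis (which *is* the protein axis), a full Trp34
sidechain with its six-ring centroid at the pocket origin, and Asp35/Asp153
carboxylates flanking the pocket 6.4 Å apart (far enough that an H-bond
satisfied at one never registers at the other). Requested H-bond distances,
π-stack distance/angle and buried-carbon counts are realized exactly, then
the whole complex is rigidly rotated/translated by a seed-determined
isometry. Every construction is self-verified against the package's own
detectors (requested interactions present at the requested geometry within
0.05 Å / 2°, no spurious ones, minimum inter-atomic distance 1.0 Å);
unrealizable requests raise a construction error.

### Flip trajectory (`gen_flip_trajectory`)

A two-state Markov chain over {flip-in, flip-out}. Leaving rates are
q·(1−π) from flip-in and q·π from flip-out with q scaled so the larger stay
probability equals `p_stay`; this makes the stationary flip-in occupancy
exactly π = `stationary_flip_in` (defaults 0.98 and 0.9: a mostly-locked
orientation with occasional excursions, frames every 0.1 ns). Each state
maps to a (χ1, χ2) center — (−65°, 95°) flip-in, (−177°, −100°) flip-out —
with 8° Gaussian angular noise; per-frame residue coordinates are rebuilt
from the χ values on demand. Occupancy converges to π by the chain's
ergodicity; at 2×10⁴ frames the test tolerance of ±0.02 corresponds to
about 2.7 standard deviations of the autocorrelation-corrected mean.

## Numerical choices

- Ranks: average ties throughout (`scipy.stats.rankdata`), so complete rank
  columns sum to n(n+1)/2.
- Shape-query combination: maximum over queries (one strong overlay
  suffices), ties broken by mean score then ligand id; hitlist intersection
  orders by summed list position, then id. Both rules are isolated behind
  single functions.
- Kabsch superposition returns a proper rotation (det +1) by construction;
  degenerate inputs (n < 3) are rejected.
- PDB I/O (via biotite) keeps altloc blank/'A' and logs the dropped count;
  coordinates round-trip at the format's 3-decimal precision.
- Parsers raise on unknown tokens with row/line identification; censored Kd
  entries are an enum, never sentinel numerics.

## Problem sizes

The statistical suites run at 1000 ligands × 6 structures × 20 seeds for
recovery, 1000 permutations for the enrichment null, and 2×10⁴ frames for
trajectory occupancy — sizes at which the Monte-Carlo error is several times
smaller than the tested tolerances while the full suite completes in
seconds.

## Known limitations

- No docking, conformer generation, shape overlay or MD is performed; all
  physics enters only through the synthetic generators' statistical
  assumptions.
- The protein-axis definition (PCA of CA atoms) is a convention; highly
  non-globular fragments could flip the classification near the 45°
  boundary.
- π-stacking detection ignores ring aromaticity (any distance-based cycle
  counts) and T-shaped geometries.
- The published per-structure "correlation scores" of the benchmark table
  are reproducible only under a specific, partially inconsistent treatment
  (Pearson on ranks vs Kd, with the non-binding fragment excluded for the
  ApoE4 columns); the package exposes method and censoring policy as
  parameters rather than hard-coding that treatment.
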