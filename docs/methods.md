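# Methods

## Scope and model

`gdvb` models the normalized isotropic B value of each protein atom as a
linear function of purely geometric node features on an atom contact
graph.  The underlying assumptions are (i) that atomic mobility is largely
determined by local packing — how many neighbours an atom has and how
those neighbours are wired among themselves — and (ii) that after
per-structure z-scoring, one set of coefficients transfers across
structures.  The model predicts the *shape* of the B-value distribution,
not absolute Å² values: the per-structure mean and variance are removed by
normalization and cannot be recovered from geometry alone.

## Contact graph

Atoms are nodes; an edge joins atoms *i*, *j* iff the centre-to-centre
distance d(i,j) < cutoff, a **strict** inequality (a pair at exactly the
cutoff is not bonded to numerical precision anyway, but the convention is
fixed and tested).  No van der Waals radii, no periodic images; crystal
context enters only through pre-expanded symmetry-copy atoms supplied by
the user and flagged via `mark_environment`.  Environment atoms are graph
nodes and smoothing neighbours but never regression rows.  Defaults:
5.0 Å for the GDV model (the correlation plateau starts there and shorter
cutoffs are cheaper) and 7.0 Å for the contact model (the classical
optimum for the contact-number fit).  The difference is consistent with
the GDV capturing "deep" second-shell contacts: a 5.0 Å graph plus a
~1.9 Å neighbour-of-neighbour reach covers roughly the 7 Å shell.

Neighbour search uses `scipy.spatial.cKDTree`; because `query_pairs` is
inclusive at the radius, pairs at exactly the cutoff are filtered out to
preserve strictness.  The test suite checks bit-identical edge membership
against an all-pairs O(N²) reference.

## Orbit counting

Graphlets are **induced** connected subgraphs on 2–4 nodes; a node's GDV
entry for orbit k is the number of induced occurrences touching it at that
orbit (counted per occurrence, not as an indicator).  The orbit taxonomy
(15 orbits across G0–G8) is hard-coded as a table keyed by subgraph size,
edge count and within-subgraph degree, which identifies the graphlet and
the orbit simultaneously — degree sequences distinguish all nine types on
≤ 4 nodes.

The production counter computes orbits 0–3 from identities (degree;
triangle counts by sorted-adjacency intersection; induced 3-path ends and
centres by inclusion–exclusion on neighbour degrees) and orbits 4–14 by a
numba-compiled ESU enumeration: each connected 4-set is generated exactly
once by rooting at its minimum node and extending only with larger-index,
exclusive-neighbourhood vertices.  Complexity is proportional to the
number of connected 4-subgraphs (≈ N·d³ at mean degree d), comfortably
fast for the ≤ 10⁴-atom structures the dataset filters admit.

Correctness is defined by the oracle, not the formulas: an independent
brute-force enumerator iterates every 2/3/4-subset (bitmask adjacency,
explicit connectivity check, the same orbit table) and the two must agree
entrywise; the suite sweeps 200+ seeded Erdős–Rényi graphs (n ≤ 25,
p = 0.05–0.5) plus named graphs (K₃, K₄, paths, cycles, stars, paw,
diamond).  Every orbit matrix must also satisfy the multiplicity
identities Σ O₀ = 2|E|, Σ O₁ = 2 Σ O₂, Σ O₄ = Σ O₅, and in general
Σₙ O_k(n) = m_k · #(parent graphlet), with consistent tallies across the
orbits of one graphlet.  The 9-node/10-edge worked-example graph with its
fully known orbit table (including the matrix maximum, 10, at node C on
orbit O₅) is the canonical regression test; its two edges not fixed by the
path enumerations (G–H, H–I) are pinned because no other completion
reproduces the full table.

## Feature and response pipeline

Order: count → smooth → z-score (recorded in the matrix's
`transforms_applied`; the order is configurable but this is the default,
smoothing raw counts before standardization).

* **Smoothing** emulates the refinement restraint that covalently bonded
  atoms have similar ADPs: smoothed(i) = raw(i) + mean over atoms within
  2.0 Å (**inclusive** ≤, so exact covalent bond lengths are captured;
  single pass).  Atoms with no neighbour in the radius are left unchanged.
  The 2.0 Å radius is just above covalent bond lengths and independent of
  the graph cutoff.
* **Column z-scoring** uses the sample (n−1) standard deviation; constant
  columns map to zeros with a warning (and are rejected later by the
  rank check in fitting).
* **Response normalization** z-scores B per structure by default, or per
  user-specified group (chain, domain, TLS group) for structures whose B
  distribution is multimodal because rigid units sit at different overall
  mobility levels; group choice is case-dependent and deliberately left to
  the user rather than inferred by mixture fitting.

## Regression

Plain OLS (statsmodels), no regularization; t-statistics from standard
OLS inference.  Variable importance is |t| rescaled so the top variable
scores 100.  Accuracy is the Pearson correlation between predicted and
reference normalized B values (the linear-model-appropriate choice), per
structure.  Cross-validation (default tenfold) splits **entries**, never
atoms: each fold fits one pooled model on the training structures and
scores every held-out structure separately; fold assignment is a pure
function of entry order and seed.  Orbit columns are strongly collinear on
real geometry, so individual coefficient signs are not interpretable —
importance ranking is the supported summary.

The published contact-model coefficients (slope −0.64, intercept 0,
7.0 Å) are built in as the `contact` preset.  No numeric coefficient set
for the published 15-orbit fit is bundled: coefficient files are plain
key=value text (`intercept`, `O0`…`O14`, `model_kind`, `cutoff`) and users
supply their own fitted or transcribed sets.

## SIGD fitting

The shift is fixed at B₀ = 0.9 × min(B) by definition; (α, β) are then
the inverse-gamma MLE on B − B₀, solved via the profile likelihood:
β(α) = n·α / Σ(1/x) in closed form, and ψ(α) = log β(α) − mean(log x)
solved by bracketed Brent iteration from a method-of-moments start
(α₀ = mean²/var + 2).  The solver agrees with an independent generic MLE
to ~10⁻³ relative.

A property worth knowing: the 0.9 × min convention is an *estimator* of
the shift, and for a finite sample the minimum sits well above the support
boundary, so 0.9 × min generally exceeds a generating shift chosen below
it.  Simulation at n = 5000 from (α = 5, β = 40, B₀ = 15) places the
fitted shift near 16.5 and pulls the MLE to α ≈ 4.4, β ≈ 32 — a
projection under shift misspecification, not a solver error (with the
true shift fixed, α is recovered within 1%).  Recovery experiments are
therefore well-posed only when the data satisfy the convention exactly
(tested by constructing B₀ = 9 × min of the shifted draws).  Outlier
screening of fitted (α, β) against resolution requires dataset-wide
statistics, so the acceptance envelope is user-supplied bounds rather
than a built-in regression.

## Dataset QC

Entry-level inclusion rules with the published thresholds as defaults:
≤ 10 000 atoms, no missing B, no B > 200 Å², B sd ≥ 0.1 Å², Ramachandran
and rotamer Z-scores ≥ −2, plus optional selection-style rules
(resolution 1.6–2.6 Å, R ≤ 0.25, 50–500 residues).  All comparative
wording is read strictly, so boundary values pass.  Rules are evaluated
independently (failures are a union), absent optional metadata skips a
rule with a warning, and the threshold config round-trips through
key=value text.  Sequence-identity culling is out of scope (it needs
alignment, not metadata).

## Synthetic data

The generator emulates the statistical structure the regression assumes:
protein-like point sets whose normalized B values are
b₀ + F·β + N(0, σ) with F the structure's own smoothed, z-scored GDV
features.  Defaults mirror the study conditions used throughout the
tests: 2000 atoms per entry, 20 replicate entries, noise σ = 0.5 on the
normalized scale, and a raw-scale mapping B = 30 + 10·B_norm (Å²), floored
at 1.0 Å².  Geometries: `helix_like` (ideal α-helix spacing — 1.5 Å rise,
100° twist per residue, 2.3 Å radius — with four jittered atoms per
residue, σ = 1.2 Å) giving realistic ~14 contacts per atom at 5.0 Å, and
`random_cloud` (uniform in a 35 Å box).  Generating coefficients are all
negative (well-wired atoms move less) with the largest weights on the
unbranched path orbits O₄, O₁, O₅, echoing the importance ordering real
fits produce.

What synthetic tests do **not** show: real B values contain static and
experimental error components, crystal-contact bias at the surface, and
multimodal per-chain offsets; the generator has a single mode, no
symmetry mates and exactly linear truth.  Passing recovery tests
demonstrates the estimator chain is correct, not that real-data accuracy
reaches any particular level — corpus-scale evaluation requires a corpus
of re-refined experimental models.

## Numerical and design choices

* Altloc policy: keep the highest-occupancy conformer, ties to the
  lexicographically smallest altloc; hydrogens, waters and hetero
  compounds are excluded by default (toggleable); model 1 of multi-model
  files is used with a warning; ANISOU records are ignored.
* Structure parsing via gemmi (PDB and mmCIF); the PDB writer emits
  fixed-column records with the B column (cols 61–66, %6.2f) replaced and
  permits negative values so normalized scores can ride in the B column.
* Problem sizes in the test suite (graphs ≤ 25 nodes for the exhaustive
  sweep, 20 × 2000-atom entries for cross-validation checks) are chosen so
  that every oracle remains exactly computable while the statistics of
  interest are stable to the tolerances asserted.
* Degenerate inputs: empty selections, all-environment structures,
  rank-deficient designs, constant response groups and non-positive B
  minima all raise informative errors rather than propagating NaNs.

## Known limitations

Absolute-scale prediction is supported only as an explicit user-supplied
mean/sd rescale and is documented as unreliable.  Nucleic acids, ligands
and hydrogens are not modelled.  Graphlets stop at 4 nodes; no weighted or
directed variants.  Symmetry expansion must be done externally; the
package only honours environment flags on a pre-expanded model.
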