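# Methods

## The energy profile model

`eprofiler` reduces a 3D protein structure to a one-dimensional,
per-residue pseudoenergy profile and compares such profiles the way
sequences are compared — by dynamic-programming alignment with a
calibrated score. The model is a knowledge-based (inverse-Boltzmann)
potential built from a single geometric observable: whether a residue is
buried or exposed.

### Inside/outside classification

For residue *i*, let *c* be the centroid of all Cα atoms within a sphere
of radius *r* (default 5 Å) around Cα_i. Residue *i* counts as **inside**
iff

    ‖Cα_i − c‖ < r   or   (Cα_i − Cβ_i)·(Cα_i − c) < 0,

and **outside** otherwise; an isolated residue (no neighbor in the
sphere) is outside. Glycines and residues with a missing Cβ get an
ideal-geometry virtual Cβ reconstructed from the backbone N/Cα/C atoms
(1.53 Å bond, tetrahedral orientation); when backbone atoms are missing
too, only the distance criterion is evaluated.

**A documented degeneracy.** Because *c* is the centroid of points that
all lie within *r* of Cα_i, it necessarily lies within *r* of Cα_i, so
the distance criterion fires whenever at least one neighbor exists and
the disjunction collapses to "has a Cα neighbor within *r*". We keep the
rule in its literal disjunctive form — the side-chain term becomes
decisive only in non-degenerate variants — and expose `radius`,
`orientation_sign` (flips the side-chain dot-product criterion) and
`include_self` (adds Cα_i itself to the centroid) so users can explore
those variants. The batch classifier (`classify_all`, KD-tree based) and
the per-residue reference (`classify_inside`) are tested against each
other.

By default the local centroid *excludes* residue *i* itself: including
it drags *c* toward Cα_i and makes the distance criterion even less
discriminative. The centroid is unweighted — every contributing atom is
a Cα, so mass weighting would be a constant factor.

### Pseudoenergies

Counting how often each amino-acid type *i* is inside (n_in,i) versus
outside (n_out,i) over a structure set and applying the Boltzmann
inversion gives per-type pseudoenergies in arbitrary units (k_B·T is a
constant scale and is dropped):

    e*_i = −ln((n_in,i + q) / (n_out,i + q)),

with pseudocount q = 1 by default so rare types stay finite.
Burial-prone (hydrophobic) types get e* < 0, exposure-prone types
e* > 0.

Statistics are meaningful only for the protein class they were derived
from; mixing, say, membrane-protein statistics into globular-protein
analyses gives misleading energies. The **bundled table is synthetic**:
it is computed (seed 20260923, 2000 residues per type) from
burial-controlled synthetic structure sets in which each amino acid is
buried with probability logistic(KD/2.25), KD being its Kyte–Doolittle
hydropathy. That gives a plausible hydrophobicity-ordered table for
demonstrations and tests; for any biological use, derive a table from an
appropriate structure set with `eprofiler stats`.

### Residue energies and the profile

The environment Env(i) is every residue *j* ≠ *i* with
‖Cα_i − Cα_j‖ ≤ 8 Å (boundary inclusive; no sequence-separation
exclusion). The total energy of residue *i* is

    E*_i = Σ_{j ∈ Env(i)} (e*_i + e*_j) = |Env(i)|·e*_i + Σ_j e*_j,

and the energy profile of a structure is the ordered tuple of all E*_i.
Contacts are found with a KD tree (linear expected time); the
double-loop form is retained in the test suite as an oracle, together
with the pair-sum identity Σ_i E*_i = Σ_{pairs {i,j}} 2(e*_i + e*_j).
Profiles are computed per chain by default; merging chains (contacts
then cross interfaces) is available and changes energies at interfaces.

## Profile alignment and the dScore

Energies are continuous, so they are discretized before alignment: a
normal distribution is fitted (moment matching) to a reference energy
sample — by default the pooled energies of the two profiles being
aligned, sorted before fitting so the result is order-invariant — and
bin boundaries are placed at its k/n quantiles, giving n bins of equal
probability mass (default n_bins = 20). The similarity of two energies
is

    score(a, b) = s_max − |bin(a) − bin(b)|,

with s_max = n_bins by default, so the best possible pairwise score
δ = s_max is attained exactly when both energies share a bin and all
scores stay positive. Energies beyond the fitted range clamp to the edge
bins.

Alignment is standard Needleman–Wunsch (global) or Smith–Waterman
(local) with a linear gap penalty (default s_max/2). Tie-breaking in the
traceback is deterministic: diagonal, then gap in the second profile,
then gap in the first. The DP rows are vectorized via a prefix-maximum
identity valid for linear gap costs.

The raw score x_r is calibrated between the best achievable score

    x_opt(A, B) = δ·(|A| + |B|)/2

and the mean score x̄_p of n_perm (default 100) realignments of shuffled
copies of both profiles (entry order permuted, energies kept):

    dScore = −log10((x_r − x̄_p) / (x_opt − x̄_p))   [bans].

Identical profiles give x_r = x_opt and hence exactly 0 bans regardless
of the permutation outcome; scores at or below the null mean are capped
(default 10 bans). Alignments below **2.5 bans** are flagged
significant. The permutation random streams are keyed to the profiles'
bin contents rather than argument position, so dScore(A, B) =
dScore(B, A) bit-for-bit; two structurally identical profiles still
draw distinct shuffles, keeping the self-alignment null non-degenerate.

Numerical edge cases: a zero-variance energy sample cannot be binned
(degenerate-distribution error); x_opt = x̄_p makes the calibration
undefined (degenerate-null error, only reachable for profiles whose
shuffles always align perfectly).

## MEPAL — multiple energy profile alignment

1. **Distance matrix**: all profile pairs are aligned; entry (i, j) is
   the dScore, the diagonal 0.
2. **Guide tree**: UPGMA with the size-weighted average update; merge
   heights are half the merge distance, ties break on lexicographically
   smallest sorted leaf-label tuples, and the merge order is recorded
   (average linkage is reducible, so recorded heights are monotone).
   Trees export as Newick with branch lengths.
3. **Progressive alignment**: profiles are merged in guide-tree order.
   A column of one group scores against a column of another as the
   *mean* pairwise energy score over all non-gap member pairs (the mean
   matches UPGMA's averaging); gaps introduced at a merge are never
   removed. One binner, fitted to the pooled energies of all profiles,
   is used throughout so column scores are comparable across merges
   (per-merge re-estimation would make column scores depend on merge
   order).
4. **Consensus and conservation**: per column, the consensus is the
   member energy with the highest summed pairwise score to the other
   members (ties resolved toward the lower energy); conservation is the
   summed pairwise score divided by the best possible sum
   (n_pairs · δ), so 1.0 means the column is energetically invariant.
   Single-member columns report conservation 1.0 by convention.

The text report shows, in blocks, each profile's amino acids and energy
bins (base-36 glyphs), the consensus bins, and a conservation track
(` .:-=+*#%@`, `@` = fully conserved). Gaps render as `-`.

## Evaluation utilities

Profiles can be cut into sliding windows (default length 5) labelled by
an external per-residue category (secondary structure, membrane
topology); labels are hidden during clustering and used only for
scoring. Clustering is **neural gas**: prototypes adapt by distance rank
with exponentially decaying learning rate (0.5 → 0.005) and neighborhood
range (k/2 → 0.01) over 50 presentations per sample by default; as the
neighborhood collapses the update reduces to online k-means. Agreement
with the held-out labels is **normalized mutual information**
(arithmetic-mean normalization by default; min/max/geometric variants
available), and the subsample–cluster–score cycle (default 600 fragments,
100 repeats) reports mean and standard deviation. **Spearman** rank
correlation (average ranks on ties) is provided for relating dScores to
external similarity measures.

## Synthetic data

The generators produce the study conditions for every test:

- `make_helix` — ideal α-helix Cα trace (rise 1.5 Å, 100°/residue,
  radius 2.3 Å, consecutive Cα ≈ 3.8 Å) with radially outward Cβ;
  optional Gaussian coordinate jitter.
- `make_globule` — self-avoiding walk on a 3.8 Å cubic lattice that
  always steps to the free neighbor site nearest the running centroid
  (compact growth), with per-residue inward/outward Cβ marks; restarts
  on dead ends, errors after 50 restarts.
- `make_burial_set` — the parameter-recovery workhorse: target residues
  on isolated 20 Å-spaced sites, each given a 3.8 Å companion neighbor
  with probability p. Under the literal classification rule a residue is
  inside iff it has a neighbor, so the recovered e* converges to
  −ln(p/(1 − p)).
- `perturb_structure` / `perturb_profile` — seeded Gaussian noise on
  coordinates / energies.

All generators are pure functions of (spec, seed). They emulate packing
density and burial statistics, not real folds: no secondary-structure
mixture, no side-chain packing, no crystallographic noise model.
Passing tests on them demonstrates the correctness of the machinery and
its stated invariants, not biological validity of conclusions drawn with
the bundled synthetic table.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| classification radius | 5 Å | neighbor sphere for the centroid |
| contact cutoff | 8 Å | Cα–Cα environment definition, inclusive |
| pseudocount | 1.0 | keeps e* finite |
| n_bins / s_max | 20 / 20 | equal-mass bins; δ = s_max |
| gap penalty | s_max/2 = 10 | linear |
| n_perm | 100 | permutation null sample |
| significance | 2.5 bans | dScore threshold |
| dScore cap | 10 bans | non-positive calibration ratios |

Tests and the reproduction script use 60-residue helices and ≤ 30-residue
globules, 25 replicates for stochastic claims and exhaustive enumeration
up to length-5 profiles / 6-leaf trees — sizes at which the brute-force
oracles are exact and the whole suite runs in seconds.

## Known limitations

- The literal inside/outside rule is nearly binary in practice (see the
  degeneracy note); meaningful side-chain-orientation statistics require
  one of the exposed variants.
- The permutation null uses the mean of shuffled-alignment scores; no
  analytic E-values, no trimmed estimators.
- Progressive alignment has no iterative refinement; projection
  consistency between runs with different profile subsets is not
  guaranteed (only per-profile entry order is).
- mmCIF, occupancy weighting, hydrogens and solvent-accessible-surface
  burial measures are out of scope.
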