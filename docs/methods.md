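# Methods

This note records the models, parameter choices, numerical details, and
known limitations behind `zpevol`. It is the package's own account of its
science; every empirical statement here is recomputed by the test suite or
by `scripts/acceptance.py`.

## Setting

ZP modules are two-domain extracellular units: a polymerizing ZP-N domain
followed by a regulatory ZP-C domain, each stabilized by conserved disulfide
bonds. Two evolutionary signals motivate the pipeline: (i) clade-wide loss
of the ZP-N domain, leaving standalone ZP-C proteins, visible as
domain-specific missing data in a trimmed alignment; and (ii) rewiring of
the ZP-C disulfide network, visible as presence/absence changes at
homologous cysteine alignment columns and as spatial proximity changes in
structural models. Both signals are only interpretable on a phylogeny, and
the phylogeny itself must be qualified by alignment uncertainty — hence the
replicate-alignment support machinery.

## Branch support across replicate alignments

Replication is over *alignments* of the same sequence set (a stochastic
aligner run repeatedly), not bootstrap resampling of columns. The
majority-rule consensus retains exactly the bipartitions present in
strictly more than half of the replicate trees; strictness matters because
splits at exactly 50% can be mutually incompatible. BRP is the retention
fraction. TBE is `mean_r(1 − δ_r/(p−1))` with the transfer distance δ
minimized over all branches of each replicate tree, trivial ones included;
this gives the standard floor (a cherry absent from a tree scores δ = 1,
and for p = 2 the per-tree score is defined as the 0/1 presence indicator).
`TBE ≥ BRP` holds branch-for-branch and is asserted in the tests over
hundreds of random replicate sets.

The transfer distance is computed in O(tree size) per branch via one
postorder pass that counts, under every node, the tips belonging to the
query bipartition; the two Hamming polarities fall out in closed form. A
brute-force oracle (explicit edge deletion, explicit symmetric differences)
verifies it on random instances.

## Robinson–Foulds variants

The normalized distance divides the symmetric difference of split sets by
its maximum attainable value given each tree's resolution (|S₁| + |S₂|);
this reproduces both boundary behaviors (0 for identical topologies, 1 for
trees sharing no internal branch) and handles polytomies without a special
case. The weighted variant Σ|l₁ − l₂| / Σ(l₁ + l₂) over the union of
non-trivial splits reduces to the normalized form when all internal branch
lengths are equal and shared-split lengths match. The normalization choice
is recorded in output metadata because other conventions (2n − 6
denominators) exist.

## MAD rooting

For a candidate root at relative position ρ on a branch, each tip pair
(b, c) contributes |2·d(a, b)/d(b, c) − 1| where a is the pair's ancestor
relative to the root — the root point itself for spanning pairs, the
ordinary MRCA otherwise. Same-side pair terms are independent of ρ, and the
spanning-pair sum is quadratic in ρ, so the per-branch optimum is the
closed-form minimizer `x* = Σ[(d_bc − 2 d_ib)/d_bc²] / (2 Σ 1/d_bc²)`
clamped to the branch; the global root is the branch with the smallest RMS
deviation. A 10⁻³-step grid search over every branch, evaluated by an
independent BFS-on-augmented-graph implementation, agrees with the closed
form to 10⁻⁶ in deviation in the tests.

Degenerate inputs: identical tips (d(b,c) = 0) are skipped with a warning;
all-zero branch lengths are a rooting error; ties within 10⁻¹² of the
minimum are all reported, with the lexicographically smallest smaller-side
tip set selected. The deviation is invariant to uniform branch-length
scaling and to tip order, and equals 0 exactly when some root position
makes the tree ultrametric. On 16-tip clocklike trees with 5%
multiplicative length noise, the true root branch is recovered in ≥ 95 of
100 trials (the acceptance script prints the realized rate).

## Neighbor-joining fallback

The pipeline consumes externally estimated trees when given; otherwise it
builds NJ trees from missing-aware p-distances (sites with a gap or
ambiguity in either sequence are excluded per pair; a pair with no
comparable sites is an error, never a silent zero). Ties in the Q
criterion break by the lexicographically smallest pair of cluster labels,
so the result is deterministic; negative branch lengths are clamped to 0.
This is plumbing so the pipeline runs end to end — it is not a substitute
for likelihood-based tree estimation on real data.

## Gap profiles and domain-loss calls

Columns are 1-based and intervals closed. Gap ('-', with '.' normalized on
input) and ambiguous (X, ?) characters both count as missing; B/Z/U are
residues. Domain intervals come from cysteine anchors (ZP-N = [1, 80],
ZP-C = [105, 218] by default); because replicate alignments jitter columns
by a few positions, anchors are re-located per replicate as the nearest
column within ±3 of the nominal position whose cysteine fraction is ≥ 0.5,
falling back to the nominal column.

Loss calls use clade tip-medians: ≥ 0.70 in the focal domain, ≤ 0.30 in
every other domain, ≥ 4 tips, with maximality (no call nested in another).
The median resists single aberrant tips; the maximality rule reports a
whole loss subfamily once. High-gap tips outside every call are reported
separately as outliers — likely artifactual truncations. The thresholds are
the package's operationalization of a qualitative pattern (loss clades near
80–99% gap against a ~7% background leave a wide margin) and are
configurable and recorded in every report. An unrooted input tree is
MAD-rooted first, and this is logged.

## Cysteine registry and connectivity types

The registry names homologous cysteine columns: Cys1:1, Cys2:29, Cys3:48,
Cys4:80 (ZP-N); Cys5:146, Cys6:164, Cys7:201, Cys8:{215, 218}, CysA:206,
CysB:210 (ZP-C); plus lineage-specific sites IHP_A:105, IHP_B:134,
T3_partner:140, AB_loop:{117, 129}, FBN1_partner:203. Presence means a C
within ±2 columns (alternative-column sites match on any alternative); the
window absorbs replicate jitter, and Cys8's two columns cover the observed
ambiguity of its placement.

Classification: IHP pair present → Type 2/3; within that group, CysA absent
with the βC partner present (and CysB retained) → Type 3, else Type 2; IHP
pair absent → Type 1. Losses of otherwise conserved bonds (Cys5–Cys7,
CysA–CysB) become flags rather than new types; patterns fitting no rule are
"atypical". The classifier is a pure function of the presence vector and is
exercised over every combination of the decision-relevant sites.

## Disulfide geometry

"Centroid" is defined as the mean of the CB and SG side-chain atoms (CA
fallback with a warning when no side chain was modeled). Calls use greedy
non-overlapping matching: repeatedly pair the closest remaining cysteines
within the 8.0 Å call threshold; leftover free pairs within 10.0 Å are
"proximal". Greedy matching was chosen over optimal weighted matching for
transparency; the tests enumerate small cases where the two could differ.
The thresholds bracket the 5–7.5 Å range typical of plausible bonds in
homology models with a margin, are configurable, and appear in all outputs.

## Fitch parsimony

Bottom-up set intersection/union with Hartigan's most-frequent-state
generalization at multifurcations (the binary case reduces to standard
Fitch); the change count is the exhaustive minimum, verified against
brute-force enumeration of all internal labelings on random 8-tip trees.
Top-down tie-break: keep the parent's state when possible, else the
lexicographically smallest state (root included), giving a deterministic
optimal labeling on binary trees. The parsimony score itself is
root-invariant, so the rooting choice does not affect the reported number
of connectivity transitions.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the study conditions at desk scale: 6
paralogous subfamilies × 5 species (tips `SF<i>_SP<j>`), 240 alignment
columns (covering the registry, max column 218), 10 replicate alignments,
~7% background missing data, two ZP-N-loss subfamilies with per-tip gap
fractions drawn from [0.80, 0.99] and realized exactly, and Type 1/2/3
assigned in contiguous blocks. Scaled-up variants (20 species per
subfamily) realize the background regime within ±2 percentage points.

Model choices, in order of consequence:

* **Substitutions** arrive as a Poisson process per site with replacement
  drawn uniformly from the 20 amino acids — a Jukes–Cantor-like process
  chosen because downstream stages consume alignments and trees, not model
  fits, and because it makes the variable-column fraction analytically
  checkable (the tests compare it against an independent event-level Monte
  Carlo). No WAG/VT exchangeabilities, no rate heterogeneity.
* **Type layouts** overwrite registry columns per tip (required sites → C,
  required-absent sites → a fixed non-cysteine). Stray cysteines arising by
  chance near registry columns are sanitized at the tips, because real ZP
  modules conserve exactly the registry cysteines and a chance C inside the
  tolerance window would not be a classification error but a generator
  artifact.
* **Types are monophyletic by construction** (the backbone nests the type
  blocks as (T1, (T2, T3))), so the planted number of type-switch branches
  is structural: one fewer than the number of types present.
* **Replicate jitter** perturbs the true alignment (gap runs slide by a
  discretized Normal(0, 1) offset clamped to ±3; the trailing flank is
  trimmed by 0–3 columns) rather than re-aligning, emulating the observed
  effect of aligner stochasticity without embedding an aligner. Only the
  trailing flank can be trimmed because the registry anchors column 1.
  Background gap blocks keep ≥ 6 columns away from registry sites so
  jitter can never displace a registry cysteine.
* **Coordinates** realize the planted geometry and nothing more: cysteine
  groups (planted pairs, then singletons) sit on a 24 Å grid, pair
  centroids are separated by a Uniform(2, 6) Å draw, and all non-planted
  cysteine pairs end up ≥ 10 Å apart (verified before emitting). There is
  no protein biophysics in these models — they stand in for homology
  models only as far as centroid distances are concerned.
* **Feature tables** draw signal-peptide / cleavage-site / GPI-anchor
  booleans at fixed prevalences (background 0.66/0.66/0.05; loss
  subfamilies 0.79/0.10/0.57), mirroring the qualitative pattern that
  standalone ZP-C subfamilies keep the signal peptide, lose the cleavage
  site, and may gain GPI anchors.

Every output is a pure function of (spec, seed); per-operation random
streams are split from the top-level seed with a counter-based scheme, and
two runs with the same spec produce byte-identical bundles.

Because the generator plants exactly the signals the detectors look for,
passing tests demonstrate *internal correctness* — that the statistics and
scanners recover a truth of the assumed form — not that real data meet the
assumptions. In particular, real aligner replicates can disagree more
radically than the jitter model, real domain loss can be partial or
mosaicked, and real homology models carry coordinate error that the
clean synthetic geometry does not.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in well under a minute of CPU: 10 replicates per bundle, 20 bundles for
loss/typing recovery (structures generated for 5 of them for the geometry
checks), 100 trees for rooting recovery, 200 replicate sets for the
TBE ≥ BRP sweep, and a single 1,783-tip tree for the full-scale bipartition
count.

## Known limitations

* ML tree inference, model selection, codon models, and homology modeling
  are out of scope; trees and coordinates are inputs (or NJ/synthetic
  stand-ins).
* The consensus tree carries no branch lengths; rooting and the loss scan
  therefore run on the focal (first-replicate) tree.
* The weighted-RF normalization and the loss/disulfide thresholds are
  package conventions, surfaced in outputs, not community standards.
* `summarize_features` assumes per-sequence coverage/feature values were
  computed upstream; aggregation of multiple HSPs into a per-subject
  coverage is the caller's responsibility.
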