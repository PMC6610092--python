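# Methods

## Model

The pipeline treats drug action as a diffusion process on the interactome.
Nodes are gene-encoded proteins; edges are undirected functional
interactions with integer confidence scores on the 0–999 STRING scale.
Edges are **dichotomized** — kept iff `score ≥ threshold` — so that a
threshold of 0 is the keep-all case of the canonical grid
(400, 600, 700, 800, 850 for gene–gene edges; 0, 100, 200, 325, 400, 500,
600, 700 for compound–gene interactions). Unscored, experimentally
asserted edge sets (BioPlex-style imports) are represented with score 999
so they survive every threshold; a sixth "unscored-edge" grid level is then
simply threshold 999 on that edge list.

The transition matrix is the row-normalised adjacency,
`W[a,b] = 1/deg(a)`. Nodes left without edges after thresholding receive a
self-loop (`W[a,a] = 1`) rather than being dropped: probability mass is
conserved and node indexing stays identical across thresholds, which keeps
profile matrices comparable between grid points. Node order is
lexicographic over gene identifiers, fixed once per graph, so all matrices
are bit-for-bit reproducible.

A compound's seed distribution is uniform over its mapped targets
(`1/k` each); target confidence scores gate *which* targets survive the
compound–gene threshold but do not weight the seed, matching the binary
1.0/0.0 assignment of the underlying model. Compounds whose targets all
fail to map are excluded, counted and reported.

**Random walk with restarts.** `pᵢ = pᵢ₋₁·W·(1−c) + c·p₀`, a row-vector
convention. The map is a contraction with factor `(1−c)`, so for `c > 0`
the fixed point `p* = c·p₀·(I − (1−c)W)⁻¹` is unique and every iterate is
a probability distribution (convex combination of distributions).
Convergence is declared when the L1 difference of successive iterates
falls below `tol` (default 1e-6; iteration cap 10 000, non-convergence is
flagged, not fatal). The closed form is implemented as a sparse LU solve
and doubles as an exact oracle for the iteration; it is the fast path for
batches (one factorization, many right-hand sides) and is disabled above
5 000 nodes to bound memory, where the iterative path takes over. On the
random graphs used in testing the iteration converges far faster than the
worst-case `(1−c)^i` bound because the error component along the
stationary direction is exactly zero; the geometric bound is still
asserted as a ceiling.

The restart grid defaults to the canonical list
0.0001 … 0.2 (14 values). `c = 1` reproduces the seed exactly (no
propagation beyond entry points).

## Preprocessing

Profiles may be log-transformed (`ln(p + ε)`, `ε = 1e-12`). The transform
compresses the extreme values of isolated non-propagating genes, which
otherwise dominate linear classifiers. ε is needed because propagated
profiles contain exact zeros on unreachable nodes; the natural-log base is
immaterial to linear decision rules up to scaling. The log flag is a grid
dimension, and profiles are cached per (thresholds, c) so both flag values
share one propagation.

## Classifiers

**MMC.** Between-class scatter `S_b` and within-class scatter `S_w` are
computed with *balanced* class weighting (each class contributes weight
1/2 regardless of size) to offset the 1:9 imbalance; the projection is the
top-k eigenbasis of the symmetric matrix `S_b − S_w` (default k = 1 for a
binary problem, exposed as a hyperparameter searched over {1, 2, 3}).
Unlike Fisher discriminants this requires no inversion of `S_w`, so it is
well-posed when genes outnumber compounds. Eigenvector signs are oriented
so the positive class projects higher, making serialized models
reproducible.

**Linear SVM.** scikit-learn's LinearSVC with `class_weight="balanced"`,
primal formulation (compounds outnumber genes at desk scale) and solver
tolerance 1e-3 — on the profile matrices used here the resulting decision
values agree with a tightly converged fit to within ~1e-3 relative, at an
order-of-magnitude lower cost. The C grid searched by the inner CV is
{0.01, 0.1, 1, 10, 100}.

**Calibration.** Both classifiers expose probabilities through a
Platt-style logistic regression (balanced weights) on their raw decision
values — fitted on out-of-fold scores when the caller supplies them, else
on training scores. Probabilities are therefore monotone in the decision
value by construction.

**Gene importance** is the Pearson correlation between each gene's profile
column and the prediction outcomes; the continuous calibrated probability
is used by default (hard labels via a flag), in the representation the
model was trained on. Zero-variance genes score 0 by convention (detected
by exact range, immune to float residue). Ensemble importance is the
arithmetic mean of per-model importance vectors; ranked lists export in
`.rnk` form for external preranked enrichment tools.

## Model selection

Stratified 10-fold outer / 5-fold inner nested cross-validation per grid
point. Inner folds select the hyperparameter (C or k) by mean inner
positive-class F1, ties going to the first grid entry; outer folds
estimate generalisation F1 and per-class accuracy of that selection rule.
The final model refits on all compounds with the averaged best
hyperparameter — geometric mean for C (a log-scale parameter), median for
the integer k. All fold assignments derive from the single run seed
(outer: the seed itself; inner: `seed·1009 + fold`), and the full fold
bookkeeping (outer test indices, inner train/validation indices) is
retained on the record so leakage-freedom is checkable after the fact.

Selection keeps every model with outer-CV F1 ≥ 0.84 by default (top-n as
an alternative), pooled across both classifier kinds, sorted by F1 with
ties broken by a settings hash. The ensemble ACL of a compound is the
arithmetic mean of member probabilities, each member scoring the compound
in its own feature space (its graph, thresholds, c, log flag); members
under which the compound has no entry points are skipped and counted, and
a compound unusable under every member gets a missing ACL with the reason.

## Food aggregation

A compound is a CBM when its ACL strictly exceeds the cutoff (default
0.7) and it is not flagged by curation (toxin list, cancer-promoting list,
or chemical-class membership in "normal metabolite" classes such as
nucleosides/nucleotides). Curation lists are plain-text inputs, never
hard-coded, so the manual step is reproducible and diffable; flagged
compounds stay in the table but never enter counts or correlations. Food
similarity is the Pearson (phi) correlation of binary CBM incidence rows
(ACL-weighted incidence behind a flag); foods with zero CBMs are excluded
from the correlation with a log entry. The edge cutoff for drawing the
food map has no canonical default and is a config field.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
content: a planted-partition interactome (module density 0.3 vs background
0.01 on 500 genes with a 40-gene module), compounds with 20–30 targets at
a 1:9 positive:negative ratio, positives drawing 70% of targets from the
module, and food compounds from a 30/70 mixture of positive-like and
negative-like samplers spread over foods with a planted richness ordering.
Edge scores are overlapping normals (module ≈ N(750, 100), background ≈
N(450, 150), clipped to [1, 999]) so the gene–gene threshold grid has a
detectable optimum; target scores ≈ N(450, 180) so the compound–gene grid
genuinely filters. A random spanning chain keeps the background connected
and any residual components are stitched with single logged edges. All
randomness flows from one seed through named substreams (interactome /
scores / tree / compounds / food), so any stage regenerates independently
and bitwise identically.

What passing tests on this generator show: the pipeline recovers planted
module structure and calibrates correctly under the null (permuted labels
reproduce the analytic baseline `2pq′/(p+q′)`). What they do not show:
performance on real interactomes with scale-free degree structure,
literature-biased edge confidence, correlated drug-target annotations, or
compound bioavailability — none of which the generator models.

## Problem sizes and numerical choices

The reference conditions used by the test suite and the acceptance script
are the 500-gene / 1 000-compound study above; the acceptance grid spans
one gene–gene threshold, two compound–gene thresholds, two restart values,
both preprocessing flags and both classifiers (16 nested CVs), with
propagation via the factorized closed form. Oracle agreement between
iterative and closed-form propagation is asserted at 1e-8 (L∞) with an
iteration tolerance of 1e-13; mass conservation at 1e-10; seed
normalisation at 1e-15; row-stochasticity at 1e-12. Fuzzy
protein-sequence matching uses edlib infix alignment with the mismatch
count taken relative to the shorter sequence (default cap 5%), after the
exact and containment tiers; infix alignment covers both the ungapped
best-offset case and near-containment with internal edits.

## Known limitations

- The closed-form solver's 5 000-node limit is a memory guard, not a
  correctness bound; genome-scale graphs run iteratively.
- MMC scatter matrices are dense (genes × genes); at genome scale the
  projection should be reformulated in the compound-span (n × n) dual,
  which is not implemented.
- The CLI executes the grid serially; `--threads` is reserved.
- InChIKey matching is exact full-string equality; no
  connectivity-layer-only fallback for stereoisomer collapse.
- Food-level outputs ignore compound concentration and bioavailability.
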