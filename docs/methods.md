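# Methods

This note records the models, numerical choices and limitations behind
`loopshift`, in the order the pipeline runs.

## Data model and coordinates

All genomic coordinates are 0-based half-open, matching BED/BEDPE/bedGraph
on disk; bin index = floor(position / bin size).  Contact matrices are
per-chromosome, cis-only, stored as the upper triangle of a symmetric
sparse matrix; lower-triangle input is mirrored and merged at
construction, and `total_contacts` counts each off-diagonal pixel once.
Inter-chromosomal loop records are skipped with a warning: every analysis
here (loops, compartments, APA) is intra-chromosomal.

## Normalization

**Subsampling.** Cross-library comparison requires equal totals; each
library is reduced to the smallest total by a multivariate hypergeometric
draw over pixels — exact sampling without replacement over individual
contact events, so a library already at the target is returned unchanged
and per-pixel retention is unbiased.

**Balancing.** "KR" balancing is implemented as the symmetric scaling
fixed point: a vector v with diag(v)·A·diag(v) having equal row sums,
found by the damped symmetric Sinkhorn iteration v ← v/√(rowsum/mean).
On symmetric non-negative matrices with support this converges to the
same doubly-balanced matrix as the Knight–Ruiz Newton scheme; tests
verify agreement with an independent alternating row/column proportional
fitting (ICE-style) oracle to 1e-4 relative.  Convergence is declared at
relative row-sum spread ≤ 1e-6 (max 3000 iterations, error with the
spread trace on failure); bins with zero marginal are masked out of the
system and stay zero.  The balanced matrix is rescaled to preserve the
raw total.  VC√ needs no iteration: O(i,j)/√(rowsum_i·rowsum_j).

**Expected model and distance normalization.** E(d) is the mean over
valid pixel positions at separation d — zero pixels count in the
denominator, masked bins do not; computed per chromosome on the same
normalization state used for quantification.  The normalized value is
(O−E)/(E+1); the +1 damps noise where E is small and keeps the transform
invertible (tests check O is reconstructed to 1e-12).  The sparse
container stores normalized values only at observed pixels; dense
consumers (APA, compartments) rebuild the implicit −E/(E+1) zeros via
`dense_distance_normalized`.

**Compartments.** Pearson correlation of the dense distance-normalized
map at 25 kb, leading eigenvector by symmetric eigendecomposition.  Bins
with zero marginal or zero variance are masked (NaN in the output, never
zero-filled); at least 50 usable bins are required.  The eigenvector sign
is arbitrary, so an orientation track (e.g. an active mark) fixes it via
the sign of the centered covariance.

## APA and window scores

Windows are (2·flank+1)² pixel blocks of a dense symmetric map centered
on the loop pixel (bin pair of the anchor midpoints), flank 10 bins at
10 kb.  Orientation: rows follow the 5′ (smaller-coordinate) anchor,
columns the 3′ anchor; "lower right" = larger row and column.  Loops
whose window would cross the diagonal (separation ≤ 2·flank) or the
chromosome edge are dropped and counted.  The aggregate is the per-pixel
median (mean available).  APA score = center / mean of the lower-right
5×5 block, as the analysis here defines it (the lower-*left* corner of
the classical convention is available behind a flag); non-positive
denominators yield a flagged NaN rather than an arbitrary value.  Meta
score = center / median of the 2×2 top-right block.  Corner categories
1–3 are mean differences (condition b − a) over the top-left,
bottom-right and top-right 5×5 corners.

Scaled multi-anchor metaplots map every loop onto a fixed grid: flanks
1:1, the inter-anchor span compressed to 10 equal bins by length-weighted
averaging (a row-stochastic weight matrix W applied as W·M·Wᵀ, exact for
integer ratios and verified against per-base upsampling oracles).
Per-loop comparison first (subtraction, or log2 fold change with a 1e-6
pseudocount on non-positive pixels), median across loops second.  Loops
spanning fewer than 10 source bins are dropped and counted.  The
upstream tooling this mirrors mentions a Manhattan-distance weighting
variant that is not specified anywhere; it is deliberately not guessed
at, and only the plain rescaling is implemented.

## Differential loops

The union merges loops whose anchor bins agree within 1 bin in both
anchors (connected components via union–find, representative from the
earliest stage).  Quantification sums the (2r+1)² neighborhood of the
loop pixel, r = 1 by default to absorb anchor jitter (r = 0 available).

The test is an exact conditional test of equal means for two replicate
groups of counts at equalized library size.  With common dispersion φ,
replicate counts are NB with size 1/φ; conditioned on the pair total s,
the group-A sum follows the Pólya (negative hypergeometric /
beta-binomial) law with parameters (s, n_a/φ, n_b/φ), which tends to
Binomial(s, n_a/(n_a+n_b)) as φ→0 — that limit is used directly at
dispersion 0.  The two-sided p doubles the smaller tail, includes the
observed outcome and caps at 1; both groups all-zero gives p = 1.  φ is
estimated across loops by method of moments, φ̂ = Σ(s²_i−m_i)/Σm_i²
floored at 0, requiring ≥2 replicates (or a supplied value).  Tests
cross-check the conditional law against `scipy.stats.betabinom` and
brute-force binomial enumeration.

Gates follow the printed thresholds: Benjamini–Hochberg FDR < 0.1 across
loops per stage pair, p < 0.05, and fold change ≥ 4 in either direction
on group mean counts with a 0.5 pseudocount per group.  Note a
consequence of the pseudocount: a loop whose true ratio is exactly 4.0
always measures (4µ+0.5)/(µ+0.5) < 4 and stays common; the gate is
effectively open only above 4.  Loops failing every pair are common;
the differential/common split is a partition of the union by
construction.

Stage assignment uses per-stage mean KR+distance-normalized frequencies:
gained → stage of maximum, lost → stage of minimum, the direction from
the sign of the largest-magnitude consecutive-stage change; exact ties
pick the earliest stage and are flagged.  A loop peaking at the baseline
stage is indistinguishable under this rule from a loss at the following
stage, which is why the synthetic generator never plants one (below).

## Anchor annotation

Occupancy pads each anchor by ±5 kb and intersects with peaks
(half-open, shared length > 0); classes both/one/none per factor are
mutually exclusive.  The shuffle test relocates every peak uniformly
within its own chromosome, length preserved, no non-overlap constraint —
chromosome-restricted placement keeps per-chromosome peak density, the
dominant confounder.  Two p-values are emitted: the literal
depletion-style count #(observed < shuffled)/n without the +1
correction, exactly as the printed rule reads, and a standard
+1-corrected enrichment p = (1+#(shuffled ≥ observed))/(n+1); they are
labeled and should not be conflated.

The taxonomy matches anchors at 1-bin tolerance (configurable):
`both_anchors_new` when neither anchor matches any prior-stage loop
anchor; `extension_one_anchor` when exactly one matches and the new
partner lies strictly outside the prior loop span on the far side of the
shared anchor; `paired_new_anchor_split` when a prior anchor pairs with
a brand-new anchor strictly inside a prior span; `other` otherwise
(including reuse of two known anchors in a new pair).  The four
categories are exhaustive and mutually exclusive on any input.

Internal-site ranking intersects two peak sets (e.g. NIPBL with RAD21),
keeps sites whose midpoint lies strictly between the anchors, maps them
to (site − anchor1 midpoint)/(anchor2 − anchor1 midpoint) ∈ (0,1), and
orders loops by left-anchor distance; multiple internal sites use the
one nearest the left anchor (counted), siteless loops trail.

## Tracks

ATAC fragments shift the 5′ end: +4 bp on plus-strand fragments (start),
−5 bp on minus-strand fragments (end), before inclusive length gates
50–115 bp (TF) and 180–247 bp (Nuc); the partition plus discards is a
disjoint cover of the input.  RPM matrices count a read in every bin it
overlaps (intersect semantics) and divide by library size in millions;
windows leaving the chromosome are masked rows.  The enhancer rule is
pure set algebra on peak sets; the TSS exclusion pad defaults to 1 kb —
the source rule's "TSS ± 1 bp" is almost certainly a typo for ±1 kb,
since a 1-bp pad excludes essentially nothing, but the literal value
remains selectable (`tss_pad=1`).  H3K9me3 calls scale input to the IP
total, then ratio IP/max(input, 1 read): the floor guards empty input
bins while IP = 4× input sits exactly on the inclusive ≥4 boundary (an
additive pseudocount would push every boundary bin just below the
threshold).  Differential bins require a ≥4-fold ratio change and are
antisymmetric under swapping stages.  Expression summaries assign a gene
to a loop when its body midpoint falls inside the loop span and report
log2((TPM+1)/(TPM_prev+1)) per gene with quartiles.

## Synthetic generator

The generator defines the study conditions all recovery tests run under.
Contact means are

    mu(i,j) = depth_scale · (|i−j|+1)^(−α) · (1 + κ·v_i·v_j) · L(i,j,stage)

with α = 1.0, compartment signs v in alternating 1-Mb blocks, κ = 0.3,
and counts Poisson(mu) per replicate; replicate depths are jittered
±10% so the dispersion estimator has something to do (overdispersion
enters between replicates, not within pixels).  Defaults: one 20-Mb
chromosome at 10 kb (2000 bins), five stages × two replicates, 2×10⁶
contacts per replicate — sizes chosen so the full pipeline runs in
minutes on one CPU while loop pixels still collect tens of counts.

Planted loops multiply a 3×3 neighborhood by 1+(m−1)·t with a Gaussian
taper t (σ = 0.8 bins) normalized to mean 1 over the footprint, so the
radius-1 aggregate enrichment equals the nominal multiplier m; an
unnormalized taper would dilute an 8-fold plant to a measured ≈3.9-fold
and silently decouple the planted truth from the fold-change gate.
Stage-specific profiles are asymmetric: a loop gained at stage s is
absent before s, peaks at m at s and persists at 35% of the excess
afterwards; a lost loop carries m before s, bottoms at exactly 1 at s
and partially re-strengthens.  This makes the truth well-defined under
the assignment rule (unique extremum, unambiguous largest step); a
symmetric peak would leave the gained/lost direction to a coin flip of
noise.  Differential loops are planted only at post-baseline stages.
Recovery fixtures use multipliers in {5, 6, 8} — all ≥4-fold as the
design requires, while clear of the pseudocount boundary effect noted
above.

Peak sets place CTCF/RAD21 at anchors of loops active per stage
(optionally pre-bound at all anchors), NIPBL∩RAD21 sites at configured
fractional positions inside loops, enhancer-mark combinations cycling
through the truth classes, and H3K9me3 IP/input tracks with 8× domains
in the first stage.  ATAC inserts mix truncated normals N(82,15) on
[30,140] (TF) and N(205,20) on [150,280] (Nuc), uniform strands, 50-bp
positional jitter.  Every generator is a pure function of (config,
seed).

What the generator does **not** emulate: TAD/insulation structure,
trans contacts, restriction-fragment geometry, mappability and GC bias,
copy-number variation, read-level errors, or correlated biological
replicate structure beyond depth jitter.  Passing recovery tests
therefore demonstrates the pipeline's logic and calibration under the
stated noise model, not performance on real libraries with those
additional artifacts.

## Numerical choices and degenerate inputs

- KR tolerance 1e-6 relative row-sum spread, 3000 iterations max.
- Exact-test p-values are discrete; with doubled tails they are
  super-uniform by up to the observed outcome's probability atom
  (≈√(2/(πs)) at conditional total s).  Calibration checks use totals
  large enough that this bias sits below the test resolution.
- Fold changes use a 0.5 pseudocount per group mean; log2FC maps use
  1e-6 on non-positive pixels; H3K9me3 uses a 1-read floor on input.
- Ties: stage assignment → earliest stage, flagged; merge → earliest
  stage's record; multiple internal sites → nearest left anchor.
- Empty inputs: empty contact file → empty matrix (total 0); all-zero
  count pairs → p = 1; zero retained APA loops → error; degenerate
  correlation rows → masked, error if fewer than 50 bins survive.

## Known limitations

- The exact NB test with a single common dispersion is deliberately
  simpler than empirical-Bayes tagwise shrinkage; the test is pluggable
  where a different engine is wanted.
- KR here is the Sinkhorn fixed point, not the Newton iteration; on
  ill-conditioned near-reducible matrices it may need many iterations
  (it errors with a trace rather than silently returning).
- The shuffle test's literal p-value (no +1 correction) can be 0; use
  the corrected enrichment p for inference.
- RPM matrices loop over anchors in Python; they are meant for panels of
  hundreds to thousands of anchors, not genome-wide sweeps.
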