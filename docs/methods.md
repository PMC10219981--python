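# Methods

## The statistical model

All inputs are binarised: a count ≥ 1 becomes 1, zeros stay 0. (The
binarisation rule is stated for counts above 1 and at 0; counts equal to 1
are mapped to 1, the only self-consistent reading for integer counts.) On
binary vectors the Pearson correlation equals the phi coefficient of the
2×2 contingency table, so every correlation in the pipeline reduces to
four counts and is computed from sparse-matrix products without
densification. Constant vectors make r undefined; such tests are flagged
and skipped, never scored as r = 0.

**Stage 1 — gene–enhancer scan.** Candidate pairs are all (gene, enhancer)
combinations on the same chromosome with the enhancer midpoint within the
cis window of the strand-aware TSS (`+` → gene start, `−` → end − 1;
gene-level extremity, the simplest reproducible TSS rule). The window test
anchors on the enhancer midpoint with an inclusive boundary, keeping the
distance definition symmetric with Hi-C binning. The correlation background
is *all* shared cells. The null is permutation of the gene-expression
vector only (the enhancer side is fixed), with a per-gene seed derived from
the global seed by `SeedSequence(seed, spawn_key=(gene_index,))` so results
are independent of iteration order and parallelisation.

**Permutation p-values and ties.** The estimator is the add-one form
p = (1 + b) / (n_perm + 1), which can never return 0. On binary data the
permuted statistic lives on a small integer grid (only the co-occurrence
count varies; the margins are fixed), so ties between permuted and observed
|r| carry real mass and the classical convention of counting ties as
exceedances is measurably conservative (type-I ≈ 0.038 at α = 0.05 in null
simulations). The default therefore draws the observed statistic's rank
uniformly within its tie group ("random" tie handling), which makes the
null distribution of p exactly uniform on its grid, reduces to the
classical estimator whenever there are no ties, and is bitwise reproducible
for a fixed seed; measured null type-I is 0.046–0.051 at α = 0.05. The
conservative convention remains available (`ties="over"`). Comparisons are
two-sided on |r| throughout, and tie detection is exact because |r|
comparisons are performed on the integer-valued centred co-occurrence
numerator.

**FDR.** Benjamini–Hochberg, one family per scan: all cis tests pooled in
stage 1, all pair tests pooled in stage 2, all partial tests pooled in
stage 3. Undefined tests propagate NaN and do not count toward the family
size. Significance requires both q < 0.05 and |r| > 0.05 (both
configurable). The absolute-value cutoff is used at both stages; a
signed-cutoff variant for stage 1 is exposed as `two_sided_r=False`.

**Stage 2 — pair scan.** Only genes with ≥ 2 significantly associated
enhancers enter; genes expressed in fewer than `min_cells = 100` cells are
excluded (a gene at exactly 100 is retained) and logged. The background is
the expressing-cell subset; records carry the canonical lexicographic
enhancer order and midpoint-to-midpoint distance. Pair p-values default to
the analytic two-sided t transform t = r·√((n−2)/(1−r²)) with n−2 df; an
optional permutation mode (`permute=N`) replicates the stage-1 null
construction for users who prefer a uniform treatment. The association-
agnostic baseline scan runs the same test over *all* cis enhancers per
gene, labels each pair by how many of its enhancers are associated with
the gene (0/1/2), and guards against combinatorial blow-up with an
explicit test cap.

**Stage 3 — partial correlation.** First-order partial correlation with
p on n−3 df, computed across all cells. Conditioning within the
expressing-cell background would be vacuous: there the binarised gene
vector is identically 1. Degenerate conditioning (|r_xz| = 1 or constant
gene) flags the record without aborting the scan. The implementation is
validated to ≥ 10 significant digits against an independent
residual-regression oracle (correlating OLS residuals of x~z and y~z).

**Combinations.** For k associated enhancers, 2^k − 1 non-empty activity
patterns are possible; a pattern counts as observed when at least one
expressing cell shows exactly it. Patterns are encoded as k-bit integers
(k ≤ 62 enforced; the widest real gene observed in this kind of data has
k ≈ 35), so counting distinct observed patterns never enumerates the 2^k
space.

**Hi-C support.** Contacts are looked up between the fixed-resolution bins
(default 5 kb, floor division) containing the two enhancer midpoints from
per-chromosome pre-normalised dump files; trans pairs are an error. The
transform is log2(c + 1): missing bin pairs must read as 0 after
transform, and the +1 pseudo-count is the dialect that makes log2 defined
at c = 0. The distance trend is removed by OLS of log-contact on log10
distance (a linear-bp covariate is available); pairs at distance 0 are
excluded from the fit. Controls mirror the second midpoint through the
first (2·m1 − m2), conserving distance exactly; controls falling below
coordinate 0 are skipped and counted. Because the residuals of an OLS fit
over the same records sum to zero, the overall fraction of positive
residuals is ~0.5 whenever planted and unplanted pairs are balanced; the
summary therefore also reports the positive-residual fraction among
significant pairs, and the paired Wilcoxon test against mirrored controls
gives the assumption-free version of "more contact than expected by
distance".

**TF sharing.** A TF is assigned to an enhancer when at least one of its
sites is fully contained in it; multiple sites of one TF collapse to set
membership. Pairs lacking any annotated TF count as sharing 0 (they are
not excluded). The significant/non-significant comparison is repeated on
distance-matched sets: non-significant pairs are visited in seeded random
order and each is matched without replacement to a uniformly sampled
significant pair whose distance differs by ≤ 5 %; unmatched records are
dropped and counted. Greedy seeded sampling was chosen because the
matching algorithm is otherwise unconstrained and this one is reproducible.

**Essentiality.** Per-gene features (observed combinations, significant
pairs, total cis enhancers regardless of association) are joined with
LOEUF and enhancer-domain scores by gene id; genes missing a score drop
out of that score's correlation only (pairwise deletion), so the two
correlations generally have different n. Spearman correlations use
mid-ranks for ties.

## The synthetic-data generator

Per cell and gene: latent state G ~ Bernoulli(`gene_expression_rate`
= 0.15); observed expression E = G · Bernoulli(1 − `dropout_rate` = 0.8);
module state A = G · Bernoulli(`module_on_rate` = 0.5). Each gene receives
1 + Poisson(3) linked enhancers (capped at 12) plus one unlinked cis
enhancer, all within ±0.9 Mb of the TSS on a snapped non-overlapping grid;
a random subset of ≥ 2 linked enhancers forms the planted co-active
module. Enhancer activity is background (Bernoulli 0.05) OR-ed with
coupling-driven activation: probability `coupling`·G (+
`coactivity_coupling`·A for module members). The activation terms combine
by OR rather than strict addition, which differs from a literal
rate-addition by O(rate²) and keeps probabilities well-defined near 1.

Defaults are chosen to emulate the data regime the method targets:
~12 % expressing cells per gene (≈ 240 of 2000 cells, comfortably above
the 100-cell filter), ~5–10 % accessible enhancer fraction, and
`coactivity_coupling = 0.5`, which by the Bernoulli-mixture identity
r ≈ m(1−m)δ²/(p̄(1−p̄)) puts within-module phi at ≈ 0.2–0.25 among
expressing cells — the effect-size range in which real co-active pairs are
reported. Setting both couplings to 0 yields the calibrated null used by
the calibration tests.

Hi-C: expected contact `base`·((d + res)/res)^(−`decay`) with
multiplicative `hic_boost` (default 3) on planted pairs, Poisson-sampled
at finite depth and rescaled; bins mirrored through each pair's first
anchor are generated too, so control lookups are not biased toward
missing data. TFBS: each module draws a pool of 30 TFs from a 155-TF
alphabet; members carry each pool TF with probability 0.8; every enhancer
additionally gets Poisson(5) random TFs. Scores: fake LOEUF decreases and
fake EDS increases linearly in planted module size, plus Gaussian noise
(sd 0.3). One global seed drives independent substreams per component, so
regenerating one artifact never perturbs another.

What the generator does *not* emulate: read-level/UMI noise, peak calling,
doublets, batch effects, co-expression of neighbouring genes, realistic
motif content, or trans contacts. Passing tests therefore demonstrate the
statistical machinery (calibration, power against planted structure,
correct plumbing), not performance on any real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script run at 2000 cells × 200 genes
(default-scale passes) and 1500 cells × 100 genes × 20 seeds (replicate
studies), with 199–1000 permutation shuffles depending on the granularity
the check needs; these sizes keep every gene above the 100-cell filter
while each run completes in seconds. The planted-pair recall floor (0.70)
was calibrated once from a 20-seed oracle study at the replicate scale
(observed recall 0.77–0.86) and then frozen. Oracle-equivalence checks
(phi vs contingency table, BH vs literal step-up, partial correlation vs
residual regression, OLS residualisation vs normal equations, interval
operations vs brute-force scans) are asserted to ≥ 10 significant digits.

Known limitations: stage-2 analytic p-values inherit the mild liberality
of the t transform on discrete data at small expressing-cell counts
(bounded below by the 100-cell filter); the false-discovery proportion at
FDR 5 % is measured at ~3 % under the default conditions. Very dense cis
architectures (hundreds of enhancers per window) make the baseline scan
quadratic — hence the explicit cap. Extremely reported p-values are kept
as true floats; any flooring (e.g. to double-precision limits) is a
display concern.
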