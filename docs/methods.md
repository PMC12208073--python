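# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  It is written for a maintainer deciding
whether a default is safe to change.

## Data model and preprocessing

Genotypes are strictly binary per cell and SNP (mutated / wildtype /
missing); zygosity is deliberately not modelled.  Hash-antibody counts are
treated as continuous after a centered log-ratio transform taken **per
antibody across cells** (count + 1 divided by the geometric mean of that
antibody's counts, log₂).  This orientation — rather than the per-cell CLR
common in CITE-seq — is used because every downstream decision compares
cells *within* one antibody against that antibody's background.  The +1
pseudocount handles zero counts; it is configurable.

Missingness filtering removes SNPs first (missing fraction > 0.40 over all
cells), then cells (> 0.40 over the retained SNPs).  The order is a design
choice: SNP panels are the noisier axis, and a handful of failed amplicons
should not drag whole cells below threshold.  Filtering is idempotent, and a
warning fires when the input's overall missing fraction exceeds 0.40 — the
regime in which the missing-data stress harness shows filtering and
disagreement with an intact baseline rising steeply.

## Hash background estimation

Each hash's CLR distribution is modelled as bimodal: unstained background
(left mode) and stained cells (right mode).  The background sample is built
by reflecting all values at or below the left mode about it, and the
positivity threshold is the empirical 95th percentile of that reflected
sample (empirical rather than density-based: it needs no tail model and is
monotone in the data).  Ties at the threshold are negative.

Modes are strict local maxima of a Gaussian KDE evaluated on a 512-point
grid, starting from the Silverman bandwidth.  When the mode count is not
two, the bandwidth moves in 25% steps — *down* when fewer than two modes are
visible, *up* when more.  Moving down in both situations cannot terminate
(shrinking a bandwidth only adds modes), so the widening direction for
over-split densities is the convergent completion of the rule; 30 steps
bound the loop.

When a hash ends up with fewer than 100 uniquely assigned cells, its
background is re-estimated robustly: left mode = median of the lower half of
the values, background = reflection of the values at or below it.  The
median is outlier-resistant when the stained mode is small, which is exactly
the situation that breaks the KDE mode geometry.  On a hash with *no*
stained population this fallback is conservative in the other direction (its
threshold sits near the upper quartile, so a minority of background cells
are called positive); the cluster-level > 50% rule absorbs these.

## SNP selection

For each ordered pair of preliminary hash groups and each SNP, the 2×2 table
of mutated/wildtype counts (missing genotypes excluded per SNP; no
imputation at this stage) is scored by the Pearson chi-square without
continuity correction.  One-sidedness is an eligibility filter — the mutated
proportion in the target group must strictly exceed the other group's — so
the statistic equals the squared one-sided two-proportion z.  Degenerate
tables (any zero margin) score 0.  The top k = 3 per ordered pair are
pooled, bounding the panel at n(n−1)k unique SNPs.  Ties break toward larger
total counts, then lexicographic SNP id, making the panel deterministic.

## Clustering and Round-1 assignment

Missing panel genotypes are imputed by majority vote of the cell's five
nearest neighbours, with neighbour distance the Hamming mismatch fraction
over panel SNPs observed in both cells; vote ties and empty votes fall back
to wildtype (the conservative call).  Cells missing every panel SNP cannot
be imputed and surface as `filtered`.

Cells are clustered agglomeratively on raw 0/1 panel vectors with cosine
distance and Ward linkage (an all-zero vector gets distance 1 to everything
— cosine is undefined there).  The dendrogram is cut into n clusters by
removing the n−1 tallest merges, keeping every cluster a subtree.  Each
subtree is then traversed downward: a node splits into its daughters when
*any* hash separates them at an equal-variance two-sample t-test p < 10⁻⁵
(unadjusted), provided both daughters have ≥ 2 cells.  Zero-variance
degeneracies: equal means → p = 1 (no split), differing means → p = 0
(split).  This rescue step exists because populations with *similar but not
identical* genotypes — doublets above all, whose genotype is the union of
two patients' — end up merged by the n-cut yet occupy their own subtree; a
population with a genotype *identical* to its neighbours has no subtree
structure for the test to find, and cannot be separated by any
genotype-tree-guided rule.  Cells excluded from the preliminary groups
(multi-positive or negative for all hashes) still enter clustering and
receive labels through their cluster.

A cluster is assigned to a hash when more than 50% of its cells strictly
exceed that hash's 95th-percentile threshold; exactly one positive hash
labels all its cells with that sample, two or more yield `multiplet`, none
`no_call`.

## Round-2 refinement by circular binary segmentation

For every hash with at least one uniquely assigned cluster, a centroid (mean
CLR vector of those clusters' cells) is computed; every cell gets one
Euclidean distance per centroid, measured in the full hash-expression space.
Within each cluster, ordered by dendrogram leaf order, each hash's distance
signal is segmented by CBS: the maximal circular two-sample t over all arcs,
accepted when its permutation p-value is below α = 0.01 (1000 permutations),
recursing into the resulting segments (minimum arc width 2; segments shorter
than 4 stop).  The changepoint superset over hashes subdivides the cluster
— within the cluster only, not globally.  Clusters with no changepoints are
left exactly as Round 1 produced them; where changepoints exist, segments of
at most 100 cells are re-scored with the same one/multiple/none verdict rule
at the 75th percentile (more permissive, for power on small segments), so a
narrow segment can flip to `multiplet` but also to a different sample or
`no_call`.  Wider segments always keep their Round-1 labels.

Numerical details of the permutation test: every visited segment draws one
child seed from the master generator before any work, and its permutations
come from a generator seeded with it, so the stream is independent of
early stopping; the loop stops early only once non-significance is certain
(exceedances already above α·nperm), leaving the accept decision identical
to full enumeration; exceedance uses a 10⁻⁹ tolerance so permutations that
tie the observed statistic exactly (e.g. within-segment rearrangements)
count regardless of floating-point path.  Signals longer than 512 points
subsample candidate boundaries to a 256-point grid shared by observed and
permuted statistics; the ≤ 512 regime is exact, which is what the
brute-force equivalence tests cover.

## Allele-depth doublet stage

A doublet's variant allele frequencies concentrate near mixture values.
Each cell's alternate/total depths are scored under two beta-binomial
mixtures (shared precision 50): singlet states {ε, 0.5, 1−ε} with the
heterozygous state smeared toward the extremes by the allelic-dropout rate
(ado = 0.05, ε = 0.01), and doublet states adding {0.25, 0.75}.  An EM over
cell-level doublet indicators updates the doublet prior (initial 0.1);
emission rates stay fixed — updating them on typical panel sizes is poorly
identified and the posterior ranking is insensitive to the prior.  Zero-depth
loci contribute nothing.  Cells with posterior > 0.5 are doublets, and the
final combination is an OR with the cluster-based calls; by construction the
multiplet set can only grow, so sensitivity rises and specificity falls
relative to the cluster-based caller on any fixed truth.  Filtered cells
stay filtered — a cell without usable genotype data is not rescued into a
multiplet call.

## Truth calling and metrics

Reference profiles come from single-sample experiments: a SNP counts when
non-missing in ≥ 60% of a reference's cells ("adequately genotyped"; the
threshold mirrors upstream coverage practice and is configurable) and in the
comparison set only when genotyped in *all* references; it is "present" when
mutated in > 0.5% of the cells genotyped there.  A multiplexed cell is a
**singlet** of sample s when its non-missing SNPs match s exactly (positives
and negatives), conflict with every other sample somewhere, and are not
exactly the union of any 2-sample combination (the subset size is
configurable upward); a **multiplet** when not a singlet but exactly such a
union; **ambiguous** otherwise, including whenever one of its mutated SNPs
is outside the comparison set.  Missing SNPs in the cell are ignored in all
three clauses — one consequence is that a cell observed only at SNPs where a
sample and a union coincide is judged a multiplet, which is the literal
reading of the rules.

Metrics are computed over cells neither filtered nor ambiguous:
total accuracy (correct / evaluated, where `no_call` is never correct),
multiplet sensitivity (called-multiplet among true multiplets), singlet
specificity (called-singlet among true singlets), and the
alternative-singlet fraction (wrong-sample share among sample-called true
singlets).  An empty evaluation set yields NaN metrics with a warning.

## Synthetic experiments

The generator emulates the processed matrices of a multiplexed run, with
truth known by construction.  Defaults, chosen once as a realistic operating
point: 40 SNPs of which 4 are private per patient (private SNPs are
clonal — present in every cell of that patient), remaining SNPs shared
variants carried by each patient independently with probability 0.25;
dropout (missing calls) at rate 0.10, inside the 5.5–17.3% range typical of
targeted leukemia panels.  Hash signals are emitted directly on the CLR
scale: per-hash raw proper-signal moments are drawn with sample-to-sample
variation and affinely adjusted (a·H + b, a and b solved analytically) to
common targets (mean 4.0, variance 1.0); improper signals are background
(mean 0, variance 0.64), plus Gaussian noise N(0, 0.5·σ²_H) when three or
more samples are pooled so the improper distributions do not coincide.
Exactly round((1−p)·C) singlets are drawn with replacement across patients
and round(p·C) multiplets from pairs of distinct patients; a multiplet's
genotype merges its parents' calls (any observed 1 → 1, else 0 — the merge
table never emits missing), and each parent's proper-hash signal has its
mean shrunk 20% and variance inflated by one-third.  A count-space emitter
(round(scale·2^CLR) − 1) supports end-to-end tests of the count-reading
path, and `simulate_allele_depths` builds companion depth matrices
(Poisson total depth, binomial alternate depth at the state VAFs) for the
doublet stage.

What the generator does *not* emulate: subclonal structure within a patient,
correlated dropout across amplicons, batch effects in antibody staining,
within-sample doublets, and doublet hash distributions beyond the first two
moments.  Passing the end-to-end tests therefore shows the pipeline recovers
planted structure under realistic noise levels, not that real experiments
reach the same accuracy.

## Cell-yield model

The yield simulator draws, per replicate: evaluable input cells C from a
Gaussian (mean 5300, sd 2500) clipped below at 1500; multiplet loss
P_m ~ N(0.1 + 0.025·S, 0.067²) clipped to [0, 1]; minimum sample share
P_min ~ N(max(0.33 − 0.04·S, 0.02), 0.070²) with draws floored at 0.02; and
reports, over 10 000 replicates, the probability that
C_min = C·(1−P_m)·P_min reaches thresholds of 100–500 cells for 2–8
multiplexed samples.  Clipping (not rejection resampling) implements the
C ≥ 1500 truncation: rejection would inflate the mean of a distribution
whose floor sits ~1.5 sd below it by ~6%, and the clipped model is the one
whose outputs match the documented probability regime.  Slopes are
configurable; both are per multiplexed sample.

## Problem sizes in the test suite

The suite validates end-to-end recovery on a 3 × 3 × 10 grid of synthetic
experiments (S ∈ {2,3,4} × p ∈ {0.05,0.15,0.25} × 10 seeds) at C = 4000
cells, oracle equivalence of the CBS core on signals up to length 30 (full
enumeration is quadratic in length and linear in permutations), chi-square
agreement on 1000 random tables, and truth-calling agreement on all 3⁸
genotypes over 8 SNPs and 3 samples.  The missing-data stress harness runs
an 11-point removal grid at C = 1200.  These sizes keep the full suite in
the tens of minutes on one core while leaving every guarantee asserted at
the documented thresholds.

## Known limitations

* A sub-population whose genotype is bitwise identical to its cluster's
  cannot be split by the tree-guided t-test, whatever its hash signal.
* The robust background fallback mis-calibrates on hashes with no stained
  population at all (see above); such hashes also void the corresponding
  centroid in Round 2.
* CBS boundary subsampling above 512 cells can displace a changepoint by up
  to n/256 positions; narrow-segment re-evaluation is correspondingly fuzzy
  at cluster sizes in the thousands.
* The truth caller's literal union rule classifies some heavily dropped-out
  singlets as multiplets; the ambiguous class does not absorb these.
* The doublet EM assumes one shared overdispersion and uniform genotype
  priors; it is a detector, not a genotyper.
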