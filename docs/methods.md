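# Methods

## Model

Gene *i* in one accession is observed at times t₁ < … < tₙ with at least
two biological replicates per time. Read counts are modelled as negative
binomial with mean μ and variance μ + φμ², with one common dispersion φ
shared by all genes (φ = 0 is the Poisson limit). For each of the n−1
neighboring intervals the hypothesis H₀: μᵢⱼ = μᵢⱼ₊₁ is tested; the
interval is then labelled S (not rejected), I (rejected, means rising) or
D (rejected, means falling), giving the gene's *ternary model* — a point
in a discrete space of 3ⁿ⁻¹ elements. The mean FPKM profile is finally
standardized to mean 0 and sample SD 1, the *SEP*, so that profiles are
scale-free and Euclidean distance between them is meaningful.

## Exact interval test

Libraries are scaled to the geometric mean of their sizes and rounded
half-even to integer pseudo-counts. Writing A and B for the per-group
pseudo-count sums (n_a and n_b libraries), A is a sum of iid NB variables
and, conditional on T = A + B, its law no longer involves the unknown
mean: it is negative hypergeometric with shapes n_a/φ and n_b/φ
(binomial(T, n_a/(n_a+n_b)) at φ = 0). The p-value sums the conditional
probabilities of every split no more likely than the observed one, with a
relative tolerance of 1e−12 guarding probability ties against floating
noise. Splits are enumerated exactly for T ≤ 10 000; above that a normal
approximation with continuity correction, using the exact conditional
mean and variance, takes over. The test is symmetric in the two groups.

φ is estimated once per accession by maximizing the conditional
log-likelihood of the within-group splits given the group sums (groups =
time points), a quantity that is also free of the group means when
library sizes are equal. The search is golden-section on log φ over
[1e−6, 10] to 1e−4 in log φ. Externally computed p-value tables can be
substituted for the internal test, for users who prefer another tool's
normalization or dispersion machinery.

Multiple testing uses the Benjamini–Hochberg step-up, by default per
interval across genes (each contrast treated as one family; a global
option exists). S/I/D calling rejects at q < 0.01, the package-wide
default FDR for model construction; ties in the estimated means fall
back to S.

## SEP standardization

The pair (model, μ̂) is combined by *S-run smoothing*: maximal runs of
time points joined by S intervals are replaced by their arithmetic mean,
so the statistically flat stretches of the profile are flat in the SEP,
then the vector is z-scored with sample SD (ddof = 1, configurable). A
`raw` mode (z-score of μ̂ directly, no smoothing) is provided: the exact
combination rule used by the original R implementation is documented only
in another paper's supplement, so both defensible readings are exposed and
both satisfy the Σ = 0, SD = 1 contract. The result is invariant to
positive affine transforms of μ̂. A profile that is constant after
smoothing (e.g. an all-S model) cannot have SD 1; it is returned as an
all-zero SEP flagged `degenerate` and excluded from sets by default. The
peak time (`time_max_exp`) takes the earliest time on ties, for
determinism.

## Set comparison

For sets of size k and r, D_B stacks all k·r cross distances and D_W
pools the k(k−1)/2 + r(r−1)/2 within distances. Both sets must exceed
two members, otherwise D_W is nearly empty and the test undefined. The
one-tailed two-sample t-test (alternative: mean(D_B) > mean(D_W)) uses
Welch–Satterthwaite degrees of freedom by default; a pooled-variance
variant and a one-tailed Wilcoxon rank-sum corroboration are options.
Distance vectors are sorted before testing so the statistic is bitwise
symmetric under swapping the sets. The distances sharing a common member
are positively correlated, so the nominal type-I level is approximate;
under the simulator's null family (two sets of 10 drawn from one profile
family with log-normal noise, σ = 0.5) the measured rejection rate at
α = 0.05 stays under 10%, which the acceptance checks verify. P-values
should therefore be read as strong/weak evidence rather than exact tail
probabilities — consistent with using the test to flag divergent set
pairs.

## Peak matrix and enrichment

Over genes with a non-degenerate SEP in both accessions, the joint
peak-time matrix counts (time of max in A, time of max in B) pairs; the
exact percentages sum to 100 and a two-decimal rounding is used for
printed reports. Per-cell gene lists (named like `A0m0_A1m60`) feed the
enrichment step. GO enrichment is a one-sided Fisher exact test per term
on the (target/non-target) × (annotated/not) table, with E = n·K/N, the
sample cross-product odds ratio (Haldane 0.5 correction when a cell is
zero; 1 by convention on a degenerate margin), BH within each aspect
separately and a default 10% FDR report threshold. Annotations are used
as given — no propagation up the GO graph; O and E for non-leaf terms
therefore depend on the annotation file's own completeness.

## Synthetic data

The simulator emulates the target experimental design: 7 times (0–60 in
steps of 10 days after anthesis), 2 replicates, accession types
domesticated/wild/cross, NB counts with mean path walking the true
ternary model from a base mean (× f per I, ÷ f per D) scaled by per-library
depth factors around a nominal depth of 10⁷ mapped reads. Reference
recovery conditions — 500 genes, base mean 500, fold change 8, φ = 0.05 —
give ≥ 90% per-interval symbol recovery at q < 0.01. What it does *not*
emulate: gene-specific (tagwise) dispersion, composition effects that
would require TMM-style normalization, correlated genes, length-biased
counting, or low-expression dropout structure — so passing tests
demonstrate correctness of the machinery under the stated model, not
robustness to every artifact of real libraries.

## Numerical and design choices

- Pseudo-count rounding is round-half-even, for cross-platform
  determinism.
- "Consistently expressed in all accessions" = raw count sum ≥ 1 (the
  `min_total` default) within every accession's libraries; the same rule
  serves for per-accession expression. It is monotone and idempotent.
- Library sizes default to column sums when the design omits
  `mapped_reads`; supplying true depths is preferred (the simulator does).
- Normalization is total-count scaling to the geometric-mean library
  size; TMM and GLM machinery are intentionally out of scope, with the
  external p-value import as the escape hatch for users wanting exact
  parity with another tool.
- Model query patterns accept `.` as a one-symbol wildcard; description
  matching is case-sensitive substring.
- Problem sizes in the test-suite simulations (hundreds of genes,
  10⁴-replicate calibration draws, 200-replication error-rate studies)
  were chosen as the smallest sizes at which the checked properties are
  stable across seeds.

## Known limitations

- Common dispersion only; genes far from the shared φ will be over- or
  under-called.
- The set-comparison test's independence approximation (above) makes its
  p-values anticonservative in the extreme tails.
- No GO-DAG ancestor propagation; no multi-set (> 2) omnibus comparison.
- FPKM depends on annotated gene-model lengths; genes missing from the
  annotation are a hard error rather than silently dropped.
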