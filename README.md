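# sepkit

Ternary models and **Standardized Expression Profiles (SEPs)** for
replicated RNA-seq time courses.

Fruit-development (and similar) experiments measure many genotypes — e.g.
domesticated, wild and hybrid crop accessions — at an ordered grid of time
points with few biological replicates. `sepkit` turns such a genes ×
libraries count matrix into objects that are easy to query, compare and
test:

1. **Interval tests.** For each gene and each of the *n−1* neighboring
   time intervals, the null hypothesis H₀: μⱼ = μⱼ₊₁ is tested with an
   exact conditional negative-binomial test (common dispersion φ,
   variance μ + φμ²; libraries equalized to the geometric-mean size; the
   Poisson limit φ = 0 reduces to an exact binomial). P-values become
   q-values by Benjamini–Hochberg per interval.
2. **Ternary models.** Each interval is classified **S**teady (q above
   the FDR threshold, default 0.01), **I**ncreasing or **D**ecreasing by
   the direction of the estimated FPKM means — giving a string such as
   `DSSSSS` over the 3ⁿ⁻¹ model space (729 models for 7 times).
3. **SEPs.** The mean FPKM profile μ̂ᵢ (FPKM = count·10⁹ / (gene length ·
   mapped reads)) is smoothed over S-runs and standardized so that
   Σⱼ sᵢⱼ = 0 and S(sᵢ) = 1 — scale-free profiles comparable across genes
   and accessions.
4. **Set comparison.** Two SEP sets S_A (k members) and S_B (r members)
   are compared through Euclidean distances: **D_B** (all k·r cross
   pairs) versus **D_W** (the k(k−1)/2 + r(r−1)/2 within pairs, pooled),
   with a one-tailed t-test of H₀: D̄_B = D̄_W against D̄_B > D̄_W
   (Welch by default; Wilcoxon corroboration optional).
5. **Peak matrices and GO enrichment.** Joint peak-time (times × times)
   percentage matrices locate out-of-phase gene sets between two
   accessions, and Fisher-exact GO enrichment (O, E, odds, BH-q per
   aspect) characterizes them.

A seeded negative-binomial simulator with known ground-truth models makes
the whole pipeline testable without any external dataset.

## Worked example

```sh
python examples/01_simulate_and_call_models.py
```

```
simulated 300 genes x 28 libraries (2 accessions, 7 times)
...
per-interval symbol accuracy: 0.965
whole-model accuracy:         0.880
```

300 genes are simulated with random true models (8-fold change per I/D
step from a base mean of 500, φ = 0.05, 2 replicates at 7 times); the
exact tests plus q < 0.01 calling recover 96.5% of the 1800 interval
symbols. `examples/03_compare_sep_sets.py` shows the set test in both
regimes:

```
same family:    mean(D_B)=1.785 vs mean(D_W)=1.686, t=1.20, one-tailed p=0.116
mirrored L:     mean(D_B)=2.278 vs mean(D_W)=1.086, t=10.38, one-tailed p=1.71e-20
```

Two sets drawn from one profile family are not separated, while sets with
mirrored L-shaped mean profiles (early peak vs late peak, 10 members
each) are separated decisively. The other examples cover SEP estimation
and model frequencies, the joint peak-time matrix, and GO enrichment.

The same stages are scriptable through a thin CLI — `sepkit simulate`,
`test-intervals`, `seps`, `query`, `summary`, `compare`, `peaks`, `go`,
`gene-summary`, `plot` — which communicate through TSV/JSON files; run
`sepkit --help`.

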