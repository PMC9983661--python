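# Methods

## The quantity: transcriptome entropy as "liberality"

Each RNA-seq sample is reduced to its *occupation rates*: gene i's share
p_i = c_i / Σ_j c_j of the sample's mapped reads. The transcriptome
Shannon entropy

    H = − Σ_{p_i > 0} p_i · log2(p_i)   (bits)

measures how evenly the transcriptome is spread over genes. A
differentiated cell expresses a few genes intensively (low H); a cell
dedifferentiating in culture flattens its expression (high H).
Dedifferentiation is therefore operationalized as an *increase* in H and
differentiation as a decrease; this quantitative value of cellular
(de)differentiation is called **liberality**. Derived indices carried in
every result row: evenness H / log2(m) (m = observed genes) and the
effective gene number 2^H, the count of equally expressed genes with the
same entropy.

Conventions: log base 2 (bits) by default, with a natural-log option; all
comparisons must stay within one base. 0·log 0 = 0 and no pseudocounts
are added, which keeps H exactly invariant under scaling of counts.
Entropy is computed over each sample's observed genes; zero-count genes
contribute nothing either way, and the annotated total G is carried for
reporting only. Counts may be non-integer (estimated counts are
admissible); they are treated as weights. No gene-length (TPM-style)
normalization is applied by default, since occupation rates are defined
on mapped transcript counts.

### Estimators

The plug-in estimator is negatively biased under multinomial sampling at
finite library size N; the bias is roughly (m−1)/(2N ln 2) bits. The
Miller–Madow correction H + (m−1)/(2N ln 2) is available as
`estimator="miller_madow"`. At bulk RNA-seq depths (10^6–10^7 reads over
~10^4 genes) the bias is ~0.01 bits and effectively constant across
samples of similar richness, so it cancels out of slope comparisons;
plug-in is therefore the default.

## The inferential step

Whether a covariate (extract dose, or culture time) affects entropy is
tested by ordinary least squares of per-sample H on the covariate and a
two-sided t-test of slope = 0, computed from first principles via
centered sums: β̂ = Sxy/Sxx, se = √(SSE/(n−2)/Sxx), t = β̂/se, and
p = I_{df/(df+t²)}(df/2, 1/2) through the regularized incomplete beta
function. Dose enters as the decimal dilution fraction exactly as
recorded (control 0, 1/1000 → 0.001, 1/100 → 0.01); because the control's
zero dose precludes a pure log scale, an optional log10(dose + d0)
encoding is provided (d0 default 1e−4). Each strain is tested separately
and, for dose regressions, only control + extract-dilution arms enter
(midgut/cabbage arms are excluded); no multiple-testing correction is
applied across the small number of reported contrasts.

Degenerate inputs are handled explicitly: a constant covariate raises an
error; fewer than 3 samples raises an error; SSE = 0 with a nonzero slope
returns p = 0 with a `PerfectFitWarning` rather than raising, so
simulation sweeps never abort; a constant response returns β̂ = 0, t = 0,
p = 1 (this case also has SSE = 0, and the no-signal reading takes
precedence over the perfect-fit one).

## QC

Upstream read mapping is out of scope; the one mapping-quality statistic
the analysis consumes is the multi-hit rate multi/(unique+multi), used as
a reference-acceptance criterion: a rate strictly above 0.30 flags the
sample/reference. The rate is invariant under common scaling of both
totals and undefined (an error) when both are zero.

## The synthetic-data generator

The generator emulates the statistical structure of the cultured
fat-body experiments, not their sequences:

- **Base profile.** A Zipf rank-abundance law q_i ∝ i^(−s) stands in for
  the skewed differentiated transcriptome. The true in vivo
  rank-abundance shape is not known, so the exponent is an exposed
  parameter (default s = 1).
- **Differentiation axis.** Tempering p_i ∝ q_i^(1/τ) interpolates from a
  point mass (τ→0) through q (τ=1) to uniform (τ→∞); entropy is strictly
  increasing in τ, so any attainable entropy has a unique temperature,
  found by bisection on log τ to 1e−6 bits (targets within 1e−6 bits of
  log2(m) are treated as unattainable rather than returning an
  astronomically large τ).
- **Design.** For each covariate level d and replicate, the target
  entropy is H0 + β·d + ε with ε ~ N(0, noise_sd²), clipped into the
  attainable range; clipping is recorded per sample in the truth object,
  never silent, and an infeasible *noiseless* target aborts before any
  sampling. Reads are drawn Multinomial(N, p).
- **Contaminant.** An optional fraction c of reads comes from a disjoint
  block of 136 uniformly expressed viral genes (ids prefixed `NPV_`,
  sized like a baculovirus genome's ORF count), emulating the
  nucleopolyhedrovirus infection observed in real cultures. At realistic
  infection fractions (c ≲ 0.1) the mixing entropy outweighs the dilution
  of the host term, so the spike-in does not decrease profile entropy;
  the reserved prefix lets downstream filtering be exercised.
- **Determinism.** One `numpy` Generator seeded from the config drives
  everything, with samples generated in a fixed order (levels outer,
  replicates inner; per sample: noise draw, then multinomial), so a
  config + seed pair reproduces counts bit-for-bit. Per-sample substreams
  were rejected as needless complexity at desk scale.

Defaults are the study conditions the package targets: G = 14,000 genes,
doses (0, 0.001, 0.01) × 3 replicates, N = 10^6 reads per library (a
typical bulk RNA-seq depth at desk scale), H0 = 10.5 bits (a
dedifferentiated baseline, flatter than the Zipf base's ≈9.8 bits at
G = 14,000), β = −50 bits per unit dose (−0.5 bits at the 1/100 dose, a
clearly visible re-differentiation signal), noise_sd = 0.05 bits of
replicate noise. The dose acts linearly on the *entropy* scale — the
scale the regression runs on — so effect sizes are directly recoverable
by the stats module.

What the generator does **not** model: read-level error, gene-length and
GC effects, overdispersion beyond multinomial sampling, correlated
replicate structure, batch effects, and any real fat-body expression
profile. Passing tests demonstrate that the estimator and test behave
correctly under the assumed sampling model, not that real cultures obey
that model.

## Verification strategy and problem sizes

- Entropy: closed forms (uniform, point mass, dyadic), and 1,000
  randomized checks of scale/permutation invariance and the grouping
  property at 1e−12.
- Regression: an iteratively refined dense grid search over (slope,
  intercept) — run in extended precision because float64 SSE comparisons
  cannot separate slopes closer than ~√(ε·SSE/Sxx) — agrees with the
  closed form to 1e−8 on 100 random small instances, plus one fully
  hand-computed case (β̂ = 0.8, df = 2, p ≈ 0.2696).
- t tail probabilities: numerical integration of the t density for
  df 1–30 at 1e−8; the df = 1 Cauchy closed form exactly.
- Calibration: 10,000 null simulations of the 3-dose × 3-replicate
  design; the rejection count at α = 0.05 must fall in the exact binomial
  99% interval.
- Recovery: 200 seeded repetitions at G = 2,000, N = 200,000,
  β = −50 bits/unit dose, noise 0.01 bits; the 95% CI covers β in ≥ 90%
  of runs and the sign is recovered in ≥ 99%.
- Determinism: the simulate → entropy → test → plot CLI chain is
  byte-identical across runs with the same seed (SVG output pins the
  matplotlib hash salt and strips date metadata).

These sizes were chosen to make the statistical checks decisive while
keeping the whole suite fast on a single CPU.

## Known limitations

- Absolute entropy values depend on the log base and on upstream
  normalization choices; only within-base, within-pipeline comparisons
  are meaningful.
- The plug-in/Miller–Madow pair does not cover coverage-adjusted
  estimators (Chao–Shen, jackknife); at RNA-seq depths they are
  unnecessary for slope inference.
- The OLS t-test assumes homoscedastic Gaussian replicate noise on the
  entropy scale; with 3 replicates per level there is little power to
  check that assumption, which matches the small-n setting the method is
  used in.
- Multi-mapped reads enter only through the QC rate; no per-gene
  allocation of ambiguous reads is attempted.
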