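# liberality

Quantifying cellular dedifferentiation from RNA-seq with transcriptome
Shannon entropy.

Tissue explants dedifferentiate in culture: they stop concentrating
expression on their hallmark genes and drift toward a flatter, less
specialized transcriptome. This package turns that intuition into a
number. For each sample the gene *occupation rates*
p_i = c_i / Σ_j c_j are computed from a gene × sample count matrix, and
the transcriptome Shannon entropy

    H = − Σ_{p_i > 0} p_i · log2(p_i)   (bits)

serves as the diversity index — **liberality** — of the cellular state:
low in differentiated tissue (a few dominant transcripts), high after
dedifferentiation. Whether an experimental covariate (extract dose in
the medium, or hours in culture) shifts that state is tested by ordinary
least squares of per-sample entropy on the covariate with a two-sided
t-test on the slope, implemented from first principles
(β̂ = Sxy/Sxx, t = β̂/se with df = n − 2, p via the regularized
incomplete beta function).

Intended users: bioinformaticians and culture engineers who have
gene-level counts (TSV/CSV/MatrixMarket) plus a sample sheet of
covariates, and want a tested, reproducible entropy-and-slope pipeline —
including a synthetic-data generator with known ground truth for
validating every stage without sequencing anything.

## Worked example

`examples/dose_response_test.py` simulates the canonical design — an
untreated control plus 1/1000 and 1/100 extract dilutions (dose
fractions 0.001 and 0.01), three replicate cultures each — with a true
effect of −50 bits per unit dose, then runs the pipeline:

```
sample_id    H_bits    m        N
      S01  9.990750 2000 200000.0
      S02  9.993704 2000 200000.0
      S03 10.008315 2000 200000.0
      S04  9.949596 2000 200000.0
      S05  9.944344 2000 200000.0
      S06  9.937835 2000 200000.0
      S07  9.511224 2000 200000.0
      S08  9.503401 2000 200000.0
      S09  9.486998 2000 200000.0

slope      = -49.531 bits per unit dose (true: -50.0)
std error  = 0.674
t (7 df) = -73.541
p (2-sided)= 2.26e-11
```

Controls (S01–S03) sit near the 10-bit baseline; the high-dose samples
(S07–S09) have lost ≈0.5 bits of entropy. The fitted slope recovers the
simulated effect within one standard error, and the tiny p-value rejects
the null that dose does not affect entropy — the statistical signature
of extract-driven re-differentiation. The other scripts in `examples/`
show entropy basics, estimator bias (plug-in vs Miller–Madow), and the
two figure idioms (stacked occupancy bars, entropy-vs-dose scatter).

The same pipeline is scriptable from a shell:

```sh
liberality simulate --genes 2000 --libsize 200000 --doses 0,0.001,0.01 \
    --reps 3 --beta -50 --seed 7 --out-dir sim/
liberality entropy --counts sim/counts.tsv --out sim/diversity.tsv
liberality test --diversity sim/diversity.tsv --sheet sim/samples.csv \
    --covariate dose --out sim/slope.tsv
liberality plot --kind entropy_scatter --diversity sim/diversity.tsv \
    --sheet sim/samples.csv --out sim/scatter.svg
```

All tabular outputs are pure functions of inputs and flags, so repeated
runs are byte-identical.

## Package layout

- `liberality.io` — count-matrix / sample-sheet readers and writers,
  validation, multi-hit mapping QC (> 30% flags the reference).
- `liberality.diversity` — occupation rates, Shannon entropy (plug-in
  and Miller–Madow), evenness and effective gene number.
- `liberality.stats` — slope t-test from first principles, and the
  strain/treatment contrast helper.
- `liberality.simulate` — Zipf base profile, temperature flattening,
  entropy targeting by bisection, multinomial read sampling, optional
  viral-contaminant spike-in, full ground truth.
- `liberality.plots` / `liberality.cli` — figures (with render data
  exposed for numeric testing) and the thin CLI.

See `docs/methods.md` for the model, assumptions, parameter choices and
limitations.

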