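# readerdecay

Tools for asking, on fully synthetic data with known ground truth, the
question an m⁶A-reader study asks of real sequencing data: **does a reader
protein that binds N6-methyladenosine (m⁶A) marks accelerate the decay of
the transcripts it binds, in proportion to how many sites it binds?**

The package chains the five quantitative steps such a study rests on:

1. **Spike-in-calibrated m⁶A quantification.** Per sample, the methylated
   control spike-in's IP/input ratio
   `r = (CPM_IP + 0.01)/(CPM_Input + 0.01)` yields a normalization factor
   `nf = r / mean(r over wild-type samples)`, and per-feature m⁶A levels
   `(CPM_IP + 0.01)/(CPM_Input + 0.01) × nf`.
2. **Windowed peak calling** on binned IP vs input coverage, keeping
   windows with enrichment ≥ 2 and Benjamini–Hochberg FDR < 0.05 under a
   one-sided Poisson test against a local input background.
3. **Strand-aware target classification.** Binding sites and m⁶A peaks are
   intersected with a ≥ 1-nt overlap rule; genes split into
   reader-targeted, reader-and-m⁶A-targeted, and non-targeted, with
   per-gene binding-site counts and 5′UTR/CDS/3′UTR metagene fractions.
4. **mRNA half-life estimation.** After transcription shutoff, samples at
   0/15/30/60/120 min are ERCC-spike-corrected and each gene's relative
   abundance is fit to `y = exp(−A·x)` (y(0) = 1); half-life is `ln 2 / A`.
   Genotype contrasts are `log2(t½ mutant / t½ wild-type)`, stratified by
   binding-site count (1 / 2 / 3+ / non-targeted).
5. **Group statistics.** ECDFs, quartile/boxplot summaries (whiskers at
   ±1.5 × IQR), two-sided Wilcoxon rank-sum tests, and BH FDR adjustment.

A first-class synthetic-data module generates the whole study — toy
genome, negative-binomial count tables with spike-in rows, binned CLIP
coverage with 3′UTR-biased sites, decay time courses in which the
reader-loss genotype multiplies each target's decay rate by a configurable
factor per binding site — so every stage is testable against ground truth.
Translation-efficiency computation (`TE = CPM_Ribo / CPM_Input`) and
ribosome-footprint simulation are included.

## Worked example

```python
from readerdecay import PipelineConfig, SimConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    sim=SimConfig(n_genes=600, seed=1), log_level="WARNING"))
```

With the default design — half the genes methylated, half of those
reader-bound, a per-site decay-rate multiplier of 0.6 in the reader-loss
genotype — this prints (via the snippet in the repo, exact output):

```
mock CLIP/m6A peak overlap:  0.988
metagene 3'UTR fraction:     0.797
median log2 t1/2 ratio, non-targeted:  0.013  (n=457)
median log2 t1/2 ratio,            1:  0.750  (n=115)
median log2 t1/2 ratio,            2:  1.442  (n=27)
median log2 t1/2 ratio,           3+:  1.850  (n=1)
Wilcoxon p, targets vs non-targets: 6.78e-66
```

Reading the numbers: nearly every called binding site carries an m⁶A peak
(0.988, matching the generator's by-construction coupling); sites
concentrate in 3′UTRs (≈ 0.80, the configured bias); losing the reader
lengthens target half-lives — a 1-site gene by ≈ 2^0.75 ≈ 1.7-fold,
matching the configured 1/0.6, with the shift growing monotonically in
site count while non-targets stay at ≈ 0 — and the target-vs-non-target
contrast is overwhelming.

The same pipeline is scriptable from the shell:

```bash
readerdecay simulate --outdir data/ --seed 1
readerdecay run-all  --outdir run/  --seed 1
readerdecay decay-fit --counts data/decay_WT.tsv \
    --samples data/decay_WT_samples.tsv --out fits.tsv
```

## Layout

| module | contents |
| --- | --- |
| `readerdecay.synthetic` | `SimConfig`, ground truth, all simulators |
| `readerdecay.normalization` | `CountTable`, CPM, spike calibration, m⁶A level, TE |
| `readerdecay.intervals` | intervals, peak calling, intersection, classification |
| `readerdecay.decay` | course normalization, exponential fits, stratification |
| `readerdecay.stats` | Wilcoxon, ECDF, BH FDR, boxplot summaries |
| `readerdecay.io` / `.pipeline` / `.cli` | format dialects, orchestration, CLI |

See `docs/methods.md` for the model, parameter choices, and limitations.
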