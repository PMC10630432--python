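# sasvtrace

Suspended prokaryotes that also turn up in sinking particles are tracers of
ocean particle export. `sasvtrace` implements the analysis behind that idea
for 16S rRNA amplicon data: it identifies **SASVs** — amplicon sequence
variants (ASVs) found, with exactly identical sequences, both suspended in
the water column and in sinking particles collected by sediment traps — and
uses their relative abundances to quantify where exported particles form,
degrade and are colonized.

The package is aimed at microbial oceanographers with paired water-column and
sediment-trap amplicon datasets (moored trap time series or drifting-trap
expeditions). It provides:

* **SASV identification** by exact (optionally N-tolerant) sequence matching
  between trap samples and a monthly water-column climatology, or directly
  against contemporaneous water samples;
* **shared-fraction depth profiles** in both directions: the share of the
  suspended community at depth *Z* entrained in trap material, and the share
  of the trap community originating from depth *Z*;
* **power-law attenuation fits** of those profiles in the Martin-curve form

  *S*<sub>*Z*</sub> = *S*<sub>ref</sub> (*Z*/*Z*<sub>ref</sub>)<sup>*b*</sup>

  (nonlinear least squares on the linear scale, R², a t-based p-value for
  *b* = 0, two-sigma confidence intervals), per time-averaged profile and per
  trap interval, with covariate correlations for the *b* time series;
* **depth-zone ecotype classification** of abundant SASVs (≥ 0.1% of the
  water column at some depth) by their water-column depth maxima, into six
  zones from Surface (5–75 m) to Bathypelagic (2000–4000 m), with explicit
  bimodal-peak retention rules;
* **summer export pulse (SEP) analysis**: trap intervals are flagged when
  particulate C *and* N fluxes reach ≥ 150% of annual reference means, and
  per-ASV SEP enrichment is tested with Welch's t test;
* a **synthetic-data generator** that plants every one of these quantities —
  attenuation exponents, ecotype peak depths, pulsed copiotrophs, flux
  pulses, multinomial read noise — so the whole pipeline is verifiable by
  parameter recovery without any external data.

## Worked example

```python
import sasvtrace as st

cfg = st.PipelineConfig(simulate=st.SimConfig(), seed=0)
products = st.run_pipeline(cfg, "out/")
fit = products["fit_upper"]
print(f"S_75 = {fit.s_ref*100:.1f}%  b = {fit.b:.4f}  R^2 = {fit.r2:.3f}")
```

prints

```
S_75 = 82.9%  b = -1.3400  R^2 = 1.000
```

— the upper-ocean (75–250 m) attenuation fit on the default noiseless
simulation, exactly recovering the planted reference abundance (82.9% of the
suspended community shared with the trap at 75 m) and exponent
(*b* = −1.34: the trap-shared share of the suspended community falls roughly
2.5-fold between 75 and 150 m). The same products dict carries the deep
increasing fit (*b* = +0.31 below 250 m — deep suspended taxa are
increasingly entrained in particles), per-interval *b* values, depth-zone
assignments and the SEP enrichment table. The scripts in `examples/` walk
through each capability and print the numbers they compute.

The same pipeline runs from the shell on real files (TSV count tables,
FASTA, CSV metadata/flux):

```sh
sasvtrace run --config pipeline.yaml --outdir out/
sasvtrace sasv --water-counts water.tsv --trap-counts trap.tsv \
    --fasta asvs.fasta --metadata samples.csv --outdir out/
```

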