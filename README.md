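# ohfa

Analysis of 3-hydroxy fatty acid (3-OH FA) branching compositions from
bacterial culture experiments: branching-class bookkeeping, the
RIAN/RAN15/RAN17 indices, per-strain trend statistics against growth
temperature or pH, and a synthetic culture-series generator.

## What it does

- **`ohfa.profiles`** — structured fatty-acid descriptors (carbon number,
  iso/anteiso/normal branching, unsaturation, 3-hydroxylation), a parser for
  the common label dialects (`iso C_15`, `anteiso 15:0`, `16:1`, `i-C15`,
  `3-OH ai-C17`), closed relative-abundance compositions on an explicit
  normalization basis (vs. total FAs or vs. total 3-OH FAs), replicate
  aggregation to mean ± sd, and class totals restricted to the 3-OH C10–C18
  scope. "n.d." (not detected) is modeled as missing, never as zero by fiat.
- **`ohfa.quantify`** — single-point semi-quantification of peak areas
  against a deuterated injection standard (default 0.5 mg/mL × 3 µL =
  1.5 µg injected), plus a detection floor that converts sub-threshold
  values to n.d.
- **`ohfa.indices`** — `RIAN = -log10((I+A)/N)`, `RAN15 = ai-C15/n-C15`,
  `RAN17 = ai-C17/n-C17` and the plain class ratios, per replicate or from
  aggregate means, with undefined-on-zero-denominator semantics and a
  near-zero-denominator instability flag.
- **`ohfa.trends`** — replicate-level OLS trends (slope/intercept/R²/p),
  Spearman correlations, one-way ANOVA with Tukey HSD post-hoc, and inverse
  prediction from a fitted calibration with a delta-method interval.
- **`ohfa.simulate`** — generative model for culture series: log-abundance
  baselines + per-class linear condition slopes + Gaussian log-space noise,
  re-closed to 100%, floored to n.d.; presets `strainA`/`strainB`/`strainC`
  matched to the packaged fixture tables; slope recovery with confidence
  intervals.
- **`ohfa.io` / `ohfa.pipeline` / `ohfa.cli`** — long-format CSV
  interchange, six packaged checksummed fixture tables (`table1`–`table6`)
  of published mean ± sd cells, and the end-to-end pipeline.

## CLI

```sh
# generate a synthetic strain series (long CSV schema)
ohfa simulate --preset strainA --levels 5,10,15,20,25 --reps 3 --seed 42 --out sim.csv

# indices per condition level (per-replicate mean ± sd, or ratio of means)
ohfa indices --input sim.csv --mode per-replicate --out indices.csv

# per-response linear trends vs. temperature or pH
ohfa trends --input sim.csv --condition temperature --out trends.csv

# recover injected class log-ratio slopes from a simulated series
ohfa recover --input sim.csv --out recovered.csv

# full pipeline: normalized profiles, indices, trends, ANOVA/Tukey, summary
ohfa run --input sim.csv --out outdir/          # or: ohfa run --config run.yaml
```

The long CSV schema has one row per strain × condition × replicate ×
compound: `strain_id, condition_variable, condition_value, replicate_id,
basis, fa_label, value, detected` (an empty or `n.d.` value means
undetected).

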