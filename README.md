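# ripitome

Analysis pipeline for activation-induced RNA/protein interactomes built
around an immunoprecipitated splicing factor: quantitative SILAC proteomics
of the pulled-down protein complex, differential binding of the co-purified
transcripts, RNase-stratified partition of the interactome into core and
peripheral members, and immune-pathway enrichment — exercised end-to-end on
seeded synthetic data with planted truth, so every stage's recovery and
calibration are measurable.

It is written for computational biologists who work with RIP-seq /
IP-MS designs: T-cell activation studies where a protein of interest is
immunoprecipitated from resting and activated cells, with and without
RNase treatment, alongside ¹⁴N/¹⁵N metabolic labeling for relative
quantification.

## The statistics at the core

**SILAC ratio estimation.** A peptide's theoretical isotope envelope is the
convolution of per-atom isotope vectors, computed in the Fourier domain.
Each extracted mini-spectrum *y(m/z)* is fit by nonnegative least squares as

    y = A_L · P(d_light) + A_H · P(d_heavy) + ε,

where *P* projects an envelope onto the m/z grid at charge *z* (peaks at
`(M + kΔ + z·m_p)/z`). The amplitude ratio `R = A_L/A_H` is the peptide's
relative abundance; per protein, log ratios are tested against `H₀: R = 1`
with a one-sample two-sided t-test and Benjamini–Hochberg control.

**Differential expression / binding.** Counts are negative binomial with
variance `μ + φμ²`. After equalizing library sizes and estimating a common
φ by conditional maximum likelihood, each gene is tested with a conditional
exact test: given the total count `S = S_A + S_B`, the group-A share follows
a negative hypergeometric law under `H₀`, and the two-sided p-value sums all
splits no more likely than the observed one. FPKM conversion and the
log₂(FPKM) majority filters precede testing.

**Interactome partition.** Filtered protein hits (FDR < 1%, human, not on
the contaminant list) are collapsed by a majority-of-replicates detection
rule; the whole interactome is the union of untreated detections, core
members survive RNase treatment, peripheral members = whole \ core.

**Enrichment.** Upper-tail hypergeometric test of a query gene list against
each pathway of a GMT collection, BH-adjusted, with the gene universe as an
explicit argument; significant pathways export as a bipartite SIF network.

## Worked example

```bash
python analysis/02_silac_quantification.py --seed 1
```

prints

```
97 pairs matched (0 features rejected); 87 fits accepted
median relative ratio error vs planted truth: 0.35%
20/20 proteins significant at adjusted p < 0.05 (planted log2 ratio 1.0)
```

Twenty simulated proteins (~5 peptides each) carry planted abundance ratios
around 2:1 (log₂ ratio ~ N(1, 0.2)). All 97 light/heavy feature pairs pass
the co-elution and charge rules; 87 envelope fits survive the
signal-to-noise and residual screen, the accepted peptide ratios land within
0.35% (median) of the planted values at ≈50:1 signal-to-noise, and every
protein's ratio shift is detected at adjusted p < 0.05.

The other numbered scripts under `analysis/` drive the remaining stages the
same way (simulation, differential expression + splicing classes,
interactome assembly, pathway enrichment, integrated report), and

```bash
ripitome run --config config.yaml --outdir results/pipeline
```

runs everything end-to-end from a flat YAML config (keys mirror
`ripitome.simulate.SimulationConfig` plus `alpha` / `fdr_max`).

## Layout

```
src/ripitome/        library: simulate, isotopes, silac, expression,
                     interactome, enrichment, integration, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite incl. brute-force oracles and
                     end-to-end acceptance checks
scripts/acceptance.py  headline-quantity reproduction
docs/methods.md      models, defaults, design decisions, limitations
```
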