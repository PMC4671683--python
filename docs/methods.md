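# Methods

This package reimplements, as a tested pipeline over synthetic data, the
computational analysis of an activation-induced RNA/protein interactome
centered on a splicing factor: SILAC ¹⁴N/¹⁵N quantification of
immunoprecipitated proteins, differential binding/expression of the
co-purified transcripts, RNase-stratified partition of the protein
interactome, and immune-pathway overrepresentation. This note records the
models, the defaults, and the design choices that were genuinely open.

## Isotope envelopes and SILAC quantification

**Envelope model.** A peptide's aggregated isotope envelope is the
convolution of per-atom isotope abundance vectors indexed by neutron offset;
the convolution is computed in the Fourier domain
(`irfft(prod_e rfft(v_e)**count_e)`), which is exact up to floating point
and costs O(L log L) regardless of atom counts. The abundance table (C, H,
N, O, S) is a fixed constant shipped with the package so envelopes are
bit-reproducible. Metabolic ¹⁵N labeling replaces the nitrogen vector by
`(1-e, e)` at enrichment `e`; `e=None` keeps natural nitrogen, and the
unlabeled channel of the simulator uses `e=0` (pure ¹⁴N), which makes the
heavy-minus-light mass bookkeeping exact at `e=1`. Envelopes are truncated
when the remaining tail carries < 1e-12 probability, then renormalized, so
they sum to 1 within 1e-9. Correctness is pinned to a brute-force
multinomial enumeration of isotopologues (no FFT) with per-offset agreement
below 1e-9 on peptide-scale compositions.

**Projection and fitting.** Aggregated peaks sit at
`(mono + k*Δ + z*m_proton)/z` with a single effective spacing
Δ = 1.00286864 Da (between the ¹³C-¹²C and ¹⁵N-¹⁴N single-substitution
shifts; at the 0.02 m/z default line width the distinction is not
resolved). Peaks are unit-height Gaussians of configurable FWHM (default
0.02 m/z); a centroid mode snaps abundances to the nearest grid point for
exact algebraic tests. A mini-spectrum is fit as a nonnegative linear
combination of the projected light and heavy envelopes by NNLS; the ratio is
`A_light/A_heavy`. Since the original fits were screened by eye, screening
is automated with explicit thresholds: signal-to-noise (max fitted signal /
residual SD) ≥ 10, residual fraction `sqrt(RSS/Σy²)` ≤ 0.2, and no
spectral-overlap flag (raised when the two projected envelopes share more
than half of the smaller envelope's grid support, as happens at very low
enrichment). Identical projected envelopes are a singular design and raise
an error rather than returning an arbitrary split.

**Pairing rules.** Light/heavy features pair only when they carry exactly
one candidate identity, share the charge state, and co-elute within a
tolerance (default 30 s; the tolerance is not quantified in this kind of
protocol, so it is configurable). Rejections carry reason codes
(`ambiguous_identity`, `charge_mismatch`, `rt_mismatch`,
`duplicate_feature`, `unpaired`).

**Protein statistics.** Peptide ratios within a protein are
log-transformed and tested against a null ratio of 1 with a one-sample
two-sided t-test; Benjamini–Hochberg adjustment is applied across proteins
(the correction method is not named in the emulated protocol; BH is the
field default). Proteins with fewer than two finite ratios are
`untestable`; zero-spread log-ratios are `untestable-degenerate` rather
than p = 0. Ratio orientation is internally light/heavy; mapping labels to
conditions is a configuration concern because both resting/activated and
activated/resting orientations appear in this literature.

## Counts: differential expression and binding

Counts are modeled NB with variance μ + φμ². Library sizes are equalized
by linear rescaling to the geometric-mean depth (rounded pseudo-counts); a
single common dispersion is estimated by maximizing the conditional (on
per-group gene totals) log-likelihood summed over genes — the conditioning
removes the gene means, so planted signal does not bias φ. Each gene is
tested by conditioning on its total across both groups: with a common
dispersion the group-A share of the total follows a negative hypergeometric
law, and the two-sided p-value sums all splits no more likely than the one
observed (double-tail convention). The implementation is checked for exact
(1e-12) agreement against a direct `scipy.stats.nbinom` enumeration for
totals ≤ 60 and for type-I calibration (raw p < 0.05 at 0.05 ± 0.02) on
null simulations. FPKM is `count / ((length/1e3)(colsum/1e6))`; the
expressed-gene filters keep a gene when log₂(FPKM) clears a threshold (−2
for whole transcriptome, +2 for pull-down enrichment) in a strict majority
of the samples of at least one group — the printed threshold "FPKM > −2"
is only meaningful on the log₂ scale, and ties are excluded.

## Splicing score

Exon/junction intensities are scored as a splicing index
`SI = log2[(I_feature/I_gene)_B / (I_feature/I_gene)_A]`, negative when the
control condition is brighter. A reciprocal-isoform score
`(SI_inclusion − SI_exclusion)/2` flags a gene as alternatively spliced
when its magnitude exceeds 0.2 — a transparent stand-in for
reciprocal-event callers that require two correlated opposite-direction
feature changes, at the same conventional 0.2 threshold. Gene-level ratio
normalization stands in for the unspecified array-console normalization.
The score is antisymmetric under swapping condition labels.

## Interactome assembly

Hits are kept when identification FDR < 1% (strict), species is human, and
the accession is not on the contaminant list (a small default list of
keratins, digestion enzyme, antibody chains is shipped; real analyses
should pass their own). Detection per (condition, RNase state) requires a
strict majority of replicates (⌈n/2⌉ by default) — the emulated study
states no replicate rule, so the rule is explicit and configurable. The
whole interactome is the union of untreated detections over conditions;
core members are the union of RNase-treated detections; peripheral = whole
minus core. A core detection missing from the whole layer (possible under
dropout) is added to the whole set with a warning: surviving RNase
treatment implies association.

## Enrichment

Upper-tail hypergeometric test per pathway, BH across the collection,
significance at adjusted p < 0.05 (configurable; depletion is never
tested). The universe is an explicit argument — typically the
expressed-gene list — because it is the single most result-sensitive free
choice in this kind of analysis. p-values are pinned to draw enumeration
for universes ≤ 12 genes.

## Synthetic data: what it emulates and what it does not

Defaults mirror the emulated designs: 2 000 genes × 6 samples/group,
dispersion 0.1, 20% DE at |log₂FC| = 2, ~500 reads/gene; 20 proteins × ~5
tryptic-size (8–20 aa) peptides with protein-level log₂ ratios
N(1, 0.2), noise at ≈1/50 of peak signal; 6 untreated and 4 RNase-treated
MS replicates with 10% per-replicate dropout; 54 pathways of 50–200 genes
in a 10 000-gene universe with 5 planted enriched pathways and a
1 000-gene query.

Planted differential expression is applied symmetrically (2^(±lfc/2)) with
up/down genes paired at equal baselines, so the two groups carry identical
expected total abundance: total-count normalization is then exact and
non-DE genes are exactly null. Real data violate this (composition bias is
why TMM-style normalization exists), so passing calibration here validates
the exact test, not total-count normalization on skewed libraries.
Retention-time jitter stays within half the pairing tolerance by
construction (a decoy fraction violates it to exercise rejection); real
chromatography, peak shape over time, instrument-specific noise, PTM
spectra and peptide-spectrum matching are not simulated. Contaminant and
decoy hits exercise the filter logic, not the abundance structure of real
IP backgrounds.

## Numerical choices and degenerate inputs

- Envelope truncation at 1e-12 tail mass, renormalized; abundances clipped
  at 0 after the inverse FFT.
- NNLS (active set) for amplitude fitting; noiseless windows give infinite
  SNR (zero residual) and are accepted.
- Dispersion bounded to [1e-6, 10] on a log scale; φ floored at 1e-8 in
  the exact test so the Poisson limit stays numerically defined.
- Exact-test ties tolerated at 1e-10 relative in log-probability.
- Percentages round half away from zero, matching the printed style of
  67% = 143/214 and 82% = 131/159.
- BH returns values in input order, capped at 1; it rejects p outside
  [0, 1].
- Zero totals (both group sums 0) give p = 1; empty query lists give
  enrichment p = 1 for every pathway.

## Problem sizes used by the checks

Calibration checks use 2 000 genes (n = 6/group) for the count test,
800 simulated proteins (≥ 500 testable after screening) for the protein
t-test, and 1 000 uniform query draws against one 54-pathway collection for
enrichment; recovery checks use the default generator scenarios above.
These sizes give Monte-Carlo standard errors comfortably inside the
0.05 ± 0.02 calibration bands. The discrete hypergeometric and NB exact
tests are intrinsically (slightly) conservative, so their null rejection
rates sit a little below the nominal 0.05.

## Known limitations

- The common-dispersion NB test ignores gene-wise dispersion variation
  (no empirical-Bayes shrinkage); with strong dispersion heterogeneity it
  will be miscalibrated gene-by-gene.
- Total-count library normalization is exact only without composition
  bias (see above).
- The splicing reciprocity score operates on summarized feature
  intensities; it does not model probe affinity or junction read mapping.
- The aggregated-envelope approximation merges isotopologue fine
  structure; at resolutions far above the default line width a
  fine-structure model would be needed.
- The contaminant list is intentionally minimal; production use should
  supply a curated list.
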