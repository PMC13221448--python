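# slideproteo

Downstream analysis for data-independent-acquisition (DIA) proteomics of
**single-slide FFPE tumor biopsies** — the setting where one 4-µm
formalin-fixed section on a glass slide must yield a quantitative,
clinically interpretable proteome. The package implements the stages
that follow the spectral search: MS1-based peptide-amount estimation
from a HeLa dilution series, contamination/depth quality control,
median/log2 normalization, protein-signature scoring (tumor
inflammation signature, histology markers), tertile-stratified
moderated differential abundance, and pre-ranked gene-set enrichment.
A synthetic-cohort generator with full ground truth stands in for raw
instrument data, so every stage is verifiable at desk scale.

It is written for computational proteomics researchers and method
developers who need a tested, deterministic reference implementation of
this analysis chain, with explicit models where published pipelines
rely on vendor software.

## The models at the core

**Calibration.** A HeLa dilution series (10–700 ng) relates summed MS1
precursor signal to injected peptide amount via a quadratic in
log-log space,

```
log10(S) = c0 + c1·log10(a) + c2·log10(a)²
```

fitted by least squares (classical calibration: signal on amount) and
inverted on its monotone branch to estimate each sample's
"MS-based quantity of matched peptides". Out-of-range estimates are
flagged, never clamped. Injection planning follows the platform rules:
Astral 50 ng fixed; timsTOF 200 ng when available, otherwise the
remainder, but never below 50 ng.

**Contamination QC.** Skin-keratin and blood signal fractions of total
MS1, top-20 high-abundance fraction, trapezoid TIC AUC, Tukey
low-fence depth outliers, and MCM2–7 complex concordance (within-sample
SD of double-centered log2 subunit levels) quantify how ion
suppression by contaminant load erodes identification depth and
quantification quality.

**Moderated differential abundance.** For a high-vs-low tertile
contrast, each protein's pooled variance `s²` (df `d`) is shrunk toward
a trend `s0²(c)` fitted against the protein's median precursor count
`c`, with prior df `d0` estimated by trigamma moment matching:

```
s̃² = (d0·s0²(c) + d·s²) / (d0 + d),   t̃ = logFC / (s̃·√(1/n1+1/n2)),  df = d0 + d
```

followed by Benjamini–Hochberg adjustment (implemented here, verified
against statsmodels).

**Pre-ranked GSEA.** Weighted Kolmogorov–Smirnov running sum over the
fold-change ranking; ES is the signed extremum, NES normalizes by the
mean |null ES| of matching sign over random same-size gene subsets,
with a +1-continuity empirical p-value.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_estimate_amounts.py
python analysis/05_differential_enrichment.py
```

prints, for the default 68-sample cohort (seed 1):

```
identifications per sample: median 5776, range 2488-6720
keratin signal fraction: 0.009-0.743

curve: c0=2.0170 c1=0.8643 c2=-0.0071 (residual SD 0.0311)
50/68 samples inside the calibration range; median |relative error| 8.4%

PTPRC tertiles: {'high': 23, 'mid': 22, 'low': 23}
immune markers identified: 45; 62% significantly higher vs 0% lower in PTPRC-high
GSEA IFNG_RESPONSE_SYNTHETIC: ES=+0.974 NES=+3.55 p=0.0029 adj=0.00333
```

Reading: contaminated samples lose thousands of identifications (the
keratin-fraction vs depth Spearman rho is −0.95 in
`analysis/03_quality_control.py`); the calibration recovers injected
amounts to ~8% median error at 10% measurement CV; stratifying 68
samples by the pan-immune marker PTPRC gives 23-sample extreme
tertiles, and the differential/enrichment stage finds immune markers
and immune gene sets elevated in the PTPRC-high group, with essentially
none in the other direction — the asymmetry expected when the contrast
captures real immune infiltration.

The same stages are available as a CLI
(`slideproteo simulate|calibrate|qc|score|diff|gsea|run`), e.g.:

```bash
slideproteo run --seed 1 --out-dir pipeline_out
```

## Layout

- `src/slideproteo/` — library: `simulate`, `io`, `calibrate`, `qc`,
  `normalize`, `signatures`, `differential`, `gsea`, `pipeline`, `cli`
- `src/slideproteo/data/` — packaged GMT gene sets (TIS-18, histology
  markers, MCM2–7, skin keratins; `*_SYNTHETIC` sets are small curated
  stand-ins for published lists you should supply in full)
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `docs/methods.md` — model and design documentation
- `tests/` — pytest suite, including property and oracle tests
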