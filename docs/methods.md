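# Methods

## Scope and data model

The package analyzes gene-centric DIA proteomics exports: a
precursor-level long table (sample, protein symbol, peptide, MS1
area), a protein × sample quantification matrix on the linear MS2-area
scale in non-imputed and imputed variants, total-ion-chromatogram
traces, and per-sample clinical metadata. All abundances are stored
linear on disk; log transforms are explicit pipeline steps. Protein
identifiers are gene symbols throughout — no isoform handling.

## Synthetic cohort generator

The generator emulates the statistical structure of single-slide FFPE
DIA data, not its spectral detail (no m/z, retention-time or mobility
simulation, no search-engine FDR model).

**Composition.** Each sample is a mixture over six compartments: AC
tumor, SCC tumor, immune, normal epithelium, blood, and a skin-keratin
contaminant. Compartment profiles are *normalized relative signal
compositions* (each compartment's per-protein signal shares sum to 1),
so a compartment's mixture fraction equals the fraction of total MS
signal it contributes — this makes contamination load directly
interpretable and the suppression coupling exact. Tissue fractions are
Dirichlet draws whose weights depend on biopsy type (forceps biopsies
carry more normal epithelium than core/cryo needles); blood and
keratin loads are log-normal (defaults: keratin median 0.06, σ=1.0;
blood median 0.02, σ=0.8), jointly capped at 0.8. Base protein
abundances are log10-normal with SD = dynamic_range/4 (default 5
decades span); marker panels (TIS, immune, histology, MCM, keratins,
HBB/ALB) receive compartment-specific log10 boosts, e.g. +1.2 decades
for immune genes in the immune compartment. The keratin compartment
carries essentially only keratins (core skin keratins +3.5 decades),
and HBB is strongly boosted in blood so the top-20 analysis exercises
a non-keratin contaminant.

**Detection and suppression.** Detection is Bernoulli with probability
logistic in log10 relative abundance (steepness 0.25 decades). The
per-sample midpoint is solved so a clean reference mixture yields the
configured detection capacity (default 7000 of 9000 proteins,
instrument depth multiplier applied), then shifted upward by
log10(1 + suppression_strength × contaminant signal fraction),
suppression_strength = 20. Measurement noise is log-normal with CV
0.10, inflated by a factor (1 + 30 × contaminant fraction × w) where w
decays logistically with height above the detection midpoint (scale
2.5 decades) — contaminated samples quantify low/mid-abundance
proteins less precisely, which drives the MCM-concordance degradation.
These two coupling constants were fixed by a seed sweep at design time
so the intended phenomenology (keratin–depth Spearman ρ ≤ −0.5;
monotone MCM-SD rise over contamination quartiles at the 200-sample
property scale) holds robustly, and are frozen defaults.

**Masses and signal.** Biopsy length is drawn per type (forceps
shortest, cryo longest); extracted peptide mass is 25 ng/mm ×
log-normal(σ=0.35), and the estimation run injects 10% of it. Total
MS1 signal follows the quadratic calibration truth (default
c=(2, 0.9, −0.02)) in the injected amount with log-normal CV noise;
per-protein MS1 splits that total by detected relative signal, then
into 1–8 precursors per protein (geometric, shares Dirichlet-fixed per
protein). TIC traces are gamma-shaped bumps scaled so the trapezoid
AUC matches total MS1 (shape cosmetic; only the AUC is consumed).

**Missingness and imputation.** Missingness is the flip side of
detection, i.e. left-censored/abundance-dependent (MNAR). The imputed
twin fills missing cells with draws from a normal centered 1.8 sample
SDs below the sample's observed log2 mean with 0.3 SD spread — the
common global-downshift convention; it is a stand-in, not a claim
about any vendor's scheme.

**What passing tests do not show.** The generator has no batch
effects, no peptide chemistry, no shared-peptide ambiguity, no
instrument drift, and its compartment profiles are cleaner than real
tissue deconvolutions; recovery results (e.g. TIS ρ ≈ 0.9) bound what
the code does under its assumptions, not clinical performance.

## Calibration and amount estimation

log10(signal) is regressed on log10(amount) — classical calibration,
since amounts are the controlled variable of a dilution series — and
the fitted quadratic must be strictly increasing over the standard
span or the fit is rejected. Inversion solves the quadratic and keeps
the root on the increasing branch nearest the calibration range's
log-midpoint; |c2| < 1e-12 degrades gracefully to linear inversion.
Estimates outside the calibration signal span (boundaries compared
with 1e-9 relative tolerance) are flagged `extrapolated_low/high` but
reported, because real cohorts contain genuine out-of-range samples.
Injection planning: Astral fixed 50 ng; timsTOF min(200 ng,
remaining); below 50 ng remaining, `infeasible` is returned as a
status, not an error.

## Quality control

- Identification count: non-missing rows of the **non-imputed** matrix
  (identification analyses never use imputed data).
- Signal fractions (keratin set, arbitrary panels) and the top-N
  fraction (default N=20, ties broken by protein symbol) are computed
  from precursor MS1 areas, matching "MS signal" semantics rather than
  MS2 quantities. The default keratin panel
  {KRT1,2,5,6A,9,10,14,16,17} is overridable.
- TIC AUC: composite trapezoid rule (exact on piecewise-linear
  traces).
- Depth outliers: low-side Tukey fence (Q1 − 1.5·IQR); the rule tag is
  recorded in the report since other classifiers are plausible.
- Complex concordance: within each sample, the SD across complex
  members of double-centered log2 levels — the per-sample member mean
  is removed first (making the statistic exactly invariant to
  per-sample additive log shifts such as median normalization, even
  with missing cells), then each member is centered on its cohort mean
  so constant stoichiometry offsets do not read as disagreement.
  Samples with fewer than two observed members are missing.

## Normalization and scaling

Each sample's values are divided by the sample median over non-missing
cells, then log2-transformed; the back-transformed per-sample median
is exactly 1 and the operation is idempotent. Per-protein scaling is a
z-score across samples with the sample-SD (n−1) convention — the
convention is fixed and documented because "scaled" alone does not
pin it down; constant or under-observed proteins are set to zero with
a warning. Scoring and differential testing consume the imputed
matrix; identification/coverage analyses the non-imputed one. Scaling
is computed per dataset (per instrument).

## Signature scoring

A signature score is the available-case mean of scaled levels over the
signature's proteins present in the matrix; if matrix coverage of the
signature falls below `min_coverage` (default 0.5) the score is
reported missing rather than computed from a stray member or two. The
histology score is log2(mean AC-marker level) − log2(mean SCC-marker
level) on the median-normalized linear scale (arithmetic-mean
aggregation; antisymmetric under swapping panels). The packaged AC
(NKX2-1, NAPSA) and SCC (TP63, KRT5, KRT6A, DSG3) panels are editorial
defaults and user-overridable. Marker-panel coverage is the percentage
of panel genes identified anywhere in the cohort (and per sample).
Signature-row clustering uses average linkage on 1 − Spearman ρ
between protein profiles; constant profiles (undefined correlation)
are placed last with a warning. Group comparisons expose two-sided
Welch t and Wilcoxon rank-sum tests.

## Differential abundance and enrichment

Tertiles: samples ranked descending (ties broken by sample id);
n ≡ 0 (mod 3) splits evenly, n ≡ 2 gives the extra samples to the
extremes (68 → 23/22/23), n ≡ 1 to the middle. Only the high and low
tertiles are tested.

The moderated test pools within-group variance (d = n1+n2−2), fits a
variance trend against median precursor count — binned medians of
log s² over log count (unique small counts act as their own bins, ≥10
quantile bins otherwise) smoothed by a quadratic spline, with the
χ²_d median bias subtracted so the trend estimates log σ² — and
estimates the prior df d0 by trigamma moment matching of
log(s²/s0²(c)), clipped to [0.5, 500]. Posterior variance is the
df-weighted blend; t̃ has d0+d df. Limits are exact: d0=0 reproduces
the ordinary pooled t, d0→∞ pins the variance to the trend.
Zero-variance proteins get missing p with a warning; fewer than 50
proteins refuses the trend fit. BH adjustment is an in-package step-up
with missing values excluded from m (validated against statsmodels to
1e-12).

Pre-ranked GSEA uses gene-label permutation (random same-size subsets
of the ranked universe) — the standard null for a pre-ranked list;
sample permutation and adaptive multilevel p-value estimation are out
of scope. Defaults: weight 1, 1000 permutations, set size bounds
[5, 500]; all configurable and not attributed to any external tool.
NES divides ES by the mean |null ES| of matching sign; p carries the
+1 continuity correction, so the minimum attainable p is
1/(n_perm+1).

## Determinism and problem sizes

Every stochastic component draws from `numpy.random.Generator` streams
spawned from a single seed via `SeedSequence`; identical configuration
yields byte-identical written tables (provenance headers contain
version, seed and a config hash — no timestamps). The shipped analyses
and checks use a 68-sample × 9000-protein cohort (the cohort-design
default), a 200-sample cohort for quartile-level suppression
properties, 3000-protein × 5-seed null studies for test calibration,
and a 24-sample × 1200-protein configuration for the byte-identity
rerun — sizes chosen to make every property measurable in seconds on
a laptop.

## Known limitations

- The imputation downshift and the histology/immune marker panels are
  conventions, not fits to any dataset.
- d0 moment-matching uses the simple variance identity rather than a
  robust estimator; extreme variance outliers can deflate d0.
- GSEA p-values are bounded below by the permutation count.
- The pipeline tests high vs low tertiles only and supports no
  covariates or multi-group designs.
- `*_SYNTHETIC` gene sets are small curated stand-ins for published
  compendia (immune cell-type markers, hallmark immune sets,
  actionable lung-cancer markers); real analyses should supply the
  full published lists as GMT files.
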