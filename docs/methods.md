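# Methods

This note documents the statistical machinery, the defaults and the
design choices of acariscan, in the order data flows through the
toolkit.

## Probit dose–response analysis

### Model and estimation

Each vial contributes a binomial observation: `n_dead ~ Binomial(n,
P(d))` with `P(d) = c + (1 − c) Φ(α + β log10 d)`. Doses are log10
transformed; dose-0 rows are solvent controls and never enter the
probit design matrix. The default fit takes the natural response c = 0,
which mirrors how susceptible-reference toxicity tables are normally
reported; `fit(control_correction=True)` adds c as a free parameter
(logit-free, box-bounded in [0, 1)) informed by the control rows — the
appropriate option for assay designs with a surfactant-only control.

Estimation maximises the exact binomial log-likelihood with L-BFGS-B
(Nelder–Mead polish if the line search stalls), started from a least-
squares fit to empirical probits shrunk away from 0/1 by the (y+0.5)/
(n+1) correction. The covariance is the inverse of a central-difference
observed-information matrix; a test cross-checks both point estimates
and standard errors against an independent GLM (probit link) fit and a
brute-force likelihood grid search.

### Goodness of fit and heterogeneity

Lack of fit uses the Pearson χ² over the *k distinct doses* (replicate
vials pooled), with df = k minus the number of fitted parameters (k − 2
for the default fit, k − 3 when c is estimated). When χ² exceeds its
5% critical value, the covariance is inflated by the heterogeneity
factor χ²/df and confidence quantiles switch from normal to t(df). This
is Finney's convention, the one implemented by the major commercial
probit routines, and it is applied *only* under significant lack of fit
— otherwise the factor is reported as 1. Note that reports which score
goodness of fit at replicate level print larger df than the pooled
distinct-dose convention used here; the fitted line is unaffected.

### LD quantiles, intervals and the diagnostic dose

`LDp = 10^((Φ⁻¹(p) − α)/β)`, defined on the susceptibility distribution
(natural response excluded), valid only for β > 0; a non-positive
fitted slope flags the result and LD quantiles raise. Confidence
limits default to the delta method on log10 LDp,

    var(log10 LDp) = (v_αα + 2 θ v_αβ + θ² v_ββ) / β²,  θ = (Φ⁻¹(p) − α)/β,

exponentiated to give asymmetric dose-scale limits. Fieller's theorem
is available (`ci_method="fieller"`); when the slope is not
significantly positive the Fieller set is unbounded and infinite limits
are returned rather than a false interval. The published intervals this
mirrors come from software whose exact CI settings are not stated, so
neither method is privileged beyond the default.

The diagnostic dose is exactly `2 × LD90`, doubling the **unrounded**
LD90 (doubling printed 2-significant-figure LD90s reproduces published
D/D columns only to rounding, which is the observed behaviour of those
tables). Display rounding (3 significant figures) happens only in the
TSV report writer; all stored values are full precision.
`ProbitResults.from_parameters(ld50, slope)` reconstructs the quantile
machinery from published parameters alone, which is how the acceptance
script re-derives table values.

### Dose-unit conversion

`ppm_to_surface_dose(ppm, volume_ul=100, vial_area_cm2=16.39)` converts
a coating-solution concentration to the deposited surface dose,
`ppm × volume_ul × 1e−3 / area`; the defaults encode the 5-ml vial
geometry (100 μl of solution over 16.39 cm²), under which 1 ppm ≈
6.1 × 10⁻³ μg/cm².

### Single-dose monitoring

`mortality_at_dd` returns percent mortality with a Wilson 95% score
interval (informative even at 0/n and n/n) and an optional resistance
classification against a configurable mortality threshold. No threshold
is defaulted: published practice reads the heat map rather than a
binary call.

## Quantitative sequencing

### Signal ratio

`R = 100 · H_mut / (H_mut + H_wild)` over the two nucleotides
segregating at the substituted codon position only. Background peaks in
the other two channels are ignored, making the ratio scale-invariant in
trace intensity and robust to unrelated noise. If both segregating
peaks are zero the sample is unquantifiable and errors explicitly.
AB1/ABIF traces can be read (`read_ab1_peaks`) by supplying the index
of the called base; the four channel intensities at the recorded peak
location are extracted in the file's filter-wheel order. No trace
alignment or basecalling is attempted.

### Calibration and inverse prediction

Standards at resistant fractions {0, 10, 30, 50, 70, 90, 100}% (the
seven molar mixing ratios 0:10 … 10:0) are fitted by OLS of ratio on
fraction (classical calibration, the default; direct inverse regression
of fraction on ratio is available). Sample frequencies are
`(R − b)/a`, clipped to [0, 100]%, with an inverse-regression
prediction interval

    x̂ ± t_{n−2} (s/|a|) √(1 + 1/n + (x̂ − x̄)²/Sxx).

### Detection limits

The published protocol states limits "at the 95% confidence level"
without a formula; the convention here (default `prediction-band`)
defines the lower limit as the smallest frequency whose inverse-
prediction interval excludes 0% — the root of
`x − t (s/|a|) √(1 + 1/n + (x − x̄)²/Sxx) = 0` — and symmetrically the
upper limit against 100%. This is the Hubaux–Vos-style crossing-point
construction; a simpler `width-at-bound` convention (interval width
evaluated at 0 and 100) is selectable. Limits are 0 and 100 exactly
when the residual sd is 0, grow monotonically with calibration noise,
and censor estimates (`below_detection` / `above_detection`) rather
than silently reporting unquantifiable values. Censoring status is a
deterministic function of the point estimate and the limits.

### The mutation panel

The packaged panel (`data/mutation_panel.csv`) holds 18 target-site
mutations across six genes (Tuace/AChE, Tuvssc/VSSC, TuGluCl1,
TuGluCl3, TuCHS, TuCytB). On load every row is checked: codons must
differ exactly at the declared substituted position, the declared
wild/mutant nucleotides must match the codons, the transition/
transversion class must match the purine/pyrimidine identities, and the
shorthand (e.g. G228S) must encode the translated wild and mutant amino
acids at the stated codon. Cytochrome b rows translate under the
invertebrate mitochondrial code (NCBI table 5), where AGA reads Ser.

## Spearman correlation

Rho uses average ranks (Pearson on mid-ranks), identical to the
standard rank formula on tie-free data. P-values: full permutation
enumeration for n ≤ 8 (40,320 pairings at n = 8 — exact, and feasible);
the t approximation with n − 2 df above that; and a seeded Monte-Carlo
permutation test on request. Exact enumeration at the full 12-strain
panel size (12! ≈ 4.8 × 10⁸) is deliberately not the default — the t
approximation's 5%-level error at n = 12 is within the tolerance any
downstream use here requires, which the null-rate test verifies.
Correlation matrices use pairwise nd deletion per cell; cells with
fewer than 3 complete pairs or a constant margin carry nan rho rather
than failing. Significance flags are `*` (p < 0.05) and `**`
(p < 0.01) on raw p-values, matching common reporting; a
Benjamini–Hochberg column is available in the long-format output for
users who want multiplicity control.

A caution on signs: at a fixed diagnostic dose, higher resistance-
allele frequency implies *lower* mortality, so a perfect monotone
genotype–phenotype link gives ρ(frequency, mortality) = −1
(equivalently +1 against survival). Published genotype–phenotype tables
are sign-ambiguous on this point; the package reports the correlation
as computed and leaves orientation to the caller.

## Synthetic data

The generators sample from exactly the models above, so recovery tests
are well-posed:

* `simulate_bioassay` — binomial kills under the probit line; defaults
  17 mites/vial, 3 replicate vials/dose, 6 doses spanning the LD10–LD99
  of the true line (the vial-assay design the toolkit targets).
* `simulate_chromatogram` — segregating peak heights with means p·T and
  (1 − p)·T, zero-truncated Gaussian noise of sd 3% of the total signal
  T = 1000 (lognormal optional), non-segregating channels at a 2%
  baseline. The 3% default reproduces calibration r² in the high-0.99s,
  the regime working QS assays report.
* `simulate_linked_panel` — a 12-strain panel (two susceptible
  references pinned at 0% allele frequency, two resistant references at
  100%, eight field strains uniform) against the 12 panel mutations and
  4 acaricides. A strain's LD50 is the susceptible LD50 times
  `∏(1 + (RRmax − 1) p_locus)` over the acaricide's linked loci
  (RRmax = 50 by default), i.e. multiplicative per locus and additive
  across loci on the log scale; mortality is sampled at the
  susceptible-derived diagnostic dose (51 mites), and observed
  frequencies run through the full QS path (simulated standards →
  calibration → sample chromatogram → inverse prediction).

All draws come from one `numpy.random.Generator` seeded in the config:
identical configs give identical outputs.

What the generators deliberately do **not** emulate: metabolic or
toxicokinetic resistance uncorrelated with target-site genotype, gene
amplification (which decouples allele frequency from phenotype in AChE
loci), dye-dependent or sequence-context-dependent peak biases in real
chromatograms, and population-genetic dynamics. Passing recovery tests
therefore validates the estimators under their assumed models, not the
biology of any field population; on real data, genotype–phenotype
correlations can be substantially weaker than the linked-panel
simulations produce, for exactly the reasons above.

## Numerical and interface conventions

* All percentages (mortality, frequency, ratios) are serialised on the
  0–100 scale; `nd` is the literal for not-determined cells in every
  tabular output, and readers map it back to NaN.
* Probabilities inside the likelihood are clipped to [1e−12, 1 − 1e−12]
  to keep the objective finite at extreme doses.
* Writers emit fixed column orders (byte-identical reruns); readers
  address columns by name and tolerate reordering. Malformed rows are
  collected with file line numbers and never abort a batch; a missing
  required column is a schema error and does.
* Batch layers (probit over many assays, QS over a panel) convert
  per-assay failures into structured not-determined results
  (`ProbitNotDetermined`, nd cells) instead of raising.
* Heat maps annotate every cell with its value, render nd cells grey
  with an `nd` label, and always emit the underlying table as TSV; the
  TSV, not the PNG, is the deterministic artifact.

## Problem sizes used in the checks

The simulation studies shipped with the test suite use 200 assays for
the probit recovery study (6 doses × 50 mites), 1000 replicates for the
χ² null-rate check, 100 replicates for the calibration r² study, 50
replicates per fraction for QS round-trip recovery, and 600 null panels
for the Spearman type-I rate — sizes at which the Monte-Carlo error of
each checked quantity is comfortably below the margin being asserted.

## Known limitations

* The probit covariance is observed-information based; profile-
  likelihood intervals are not offered.
* Detection limits assume homoscedastic calibration residuals; real
  chromatogram noise can be intensity-dependent (the lognormal
  simulator option exists to probe this, not to fit it).
* QS inverse prediction treats the calibration as fixed when computing
  sample intervals at the usual single-new-observation level; a fully
  joint interval would be slightly wider.
* Sequencing-direction averaging is the caller's responsibility: per-
  direction peak tables are accepted and can be averaged upstream.
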