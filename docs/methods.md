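# Methods

This note documents the models, defaults and numerical choices behind
`glycovar`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator emulates a two-cohort HILIC-UHPLC glycomics study. On the
natural-log scale, the measured raw area of peak *k* in sample *i* is

    log a_ik = log b_k + Σ_{g ∋ k} d_gi + σ_peak u_ik
               + γ_{p(i),k} + σ_noise e_ik + c_i

* **b** — baseline composition (% areas summing to 100). The transferrin
  default places the published major structures at realistic shares
  (A2G2S[6,6]2 ≈ 28%, A2G2S[3,6]2 ≈ 14%, FA2G2S[6,6]2 ≈ 10%,
  A2G2S[6]1 ≈ 9%); the IgG default mirrors a typical IgG profile
  (FA2 ≈ 20%, FA2G1 ≈ 18%, FA2G2 ≈ 16%). Entries are validated to be
  positive and to sum to 100 ± 1e−9.
* **d_g** — latent of a *targeted trait group* g (the member peaks of a
  derived trait named in the effect table). For effects {(c, β_gc)} on
  standardized covariates z_c,

      d_g = σ_trait (Σ_c β_gc z_c + √(1 − Σ_c β²_gc) ε_g),

  so corr(z_c, d_g) = β_gc exactly on the latent scale. Because all member
  peaks share d_g, the noiseless derived trait carries the configured
  standardized effect up to (i) the mild log→percent nonlinearity and
  (ii) compositional closure. For a single targeted group the closure
  factor cancels in the correlation; with several targeted groups the
  largest groups (e.g. S2, ~70% of total area) bleed variance into the
  other traits' realized correlations through the shared total. This is a
  property of real % -area data, so it is deliberately not "corrected".
* **σ_peak** (default 0.05) — idiosyncratic biological log-SD per peak;
  **σ_noise** (default 0.05, ≈5% CV) — technical log-SD per measurement;
  **γ** ~ N(0, σ_batch²) per (plate, peak) with σ_batch = 0.10 — the
  multiplicative plate effect, additive on the log scale; **c_i** ~
  N(0, 0.30²) — per-sample injection scale, removed exactly by total-area
  normalization; **σ_trait** (default 0.15) — total log-SD of each targeted
  trait group. These magnitudes are chosen as typical for plate-based
  HILIC-UHPLC glycomics (technical CVs of a few percent, plate effects a
  bit larger, biology larger still).
* **Covariates.** Age ~ U(18, 90); sex Bernoulli (female share 0.65 / 0.60
  in the two presets; males coded 1 so "higher in females" is a negative
  effect); BMI log-normal (median 26.6) correlated 0.2 with age. Nine
  biochemical/physiological phenotypes (hdl, insulin, triglyc, tot_chol,
  fibrinogen, uric, hba1c, waist, and the binary arth_sr) are generated
  from a latent Gaussian with configurable loadings on age/sex/BMI and then
  marginally transformed to published-style medians/IQRs (log-normal where
  right-skewed); binary phenotypes threshold the latent at the target
  prevalence, and injected effects on them act on the latent scale.
  Phenotypes have 2% missingness by default, which is what makes
  complete-case residual DFs vary across association rows.
* **Default effect table** (transferrin preset): age → A4 +0.278,
  age → S1 −0.262, sex → B −0.331, hdl → S2 −0.129 — the strongest
  published age/sex correlations and one biochemical association, used as
  effect-magnitude anchors.
* **Plate layout.** Samples are dealt round-robin over sex × age-tertile
  strata (blocked randomization), so per-plate sex shares and age means are
  balanced by construction. Every plate carries 1 blank and 4–6 internal
  standards (pooled-plasma profile = the baseline composition, no
  biological variation). The discovery preset (927 samples, 96-well plates,
  6 standards/plate, 11.5% duplicates) yields 12 plates, 72 standards and
  107 duplicate pairs; the replication preset (958 samples, 60-well
  batches, 4 standards/plate, no duplicates) yields 18 plates and 72
  standards. Duplicates sit on their source's plate by default (flag to
  scatter them), since the placement scheme in real studies varies.

**What the generator does not emulate:** raw spectra or chromatographic
drift, co-eluting minor structures, family/kinship structure, realistic
joint phenotype distributions beyond the configured moments, or
non-Gaussian batch effects. Passing recovery tests therefore demonstrates
the *analysis chain* is correct and calibrated under the assumed generative
model, not that the model captures every feature of real cohorts.

## Chromatography

The GU calibration is a PCHIP monotone piecewise-cubic interpolant through
the dextran-ladder knots; outside the ladder it extends linearly with the
secant slope of the end interval (PCHIP endpoint derivatives can be
arbitrarily small, which would make extrapolation ill-conditioned). The
inverse map is computed by Brent root-finding on the forward map
(xtol 1e−12), so time → GU → time round-trips to < 1e−9 everywhere in the
ladder range, not only at knots. Integration uses fixed half-open GU
windows shared across samples; each window's baseline is the chord between
the boundary signal values (clipped at 0), the baseline-subtracted
trapezoidal integral is clipped at 0. Overlapping-peak deconvolution is out
of scope. The default window panels are evenly spaced synthetic
placeholders (the published per-peak GU boundaries are not public) and are
overridable via CSV.

## Preprocessing

* **Normalization**: row-wise % of total area; all-zero rows (blanks) are
  excluded with a logged warning.
* **Log transform**: natural log; zeros are imputed as half the smallest
  positive value of the same peak (standard compositional practice; the
  count is logged). This path is only reachable for degenerate inputs —
  the generator produces strictly positive areas.
* **Batch correction**: location-only empirical Bayes. Per peak the grand
  mean is the reference; per (batch, peak) the raw effect γ̂ is the batch
  mean deviation (sample-size-weighted mean zero by construction, the
  identifiability convention). Within each batch a Normal prior across
  peaks is moment-matched (prior variance = var(γ̂) − mean sampling
  variance, floored at 0) and the posterior-mean effect γ\* shrinks γ̂
  toward the batch's across-peak mean; γ\* is then re-centered so the
  per-peak grand mean is preserved exactly, and subtracted. With the prior
  made diffuse (`shrink=False`) this reduces exactly to per-batch mean
  centering — the oracle used in tests. Effects are *subtracted only*; a
  location+scale mode exists behind `adjust_scale=True` and is off by
  default. Singleton batches are warned about and left uncorrected; a
  single batch returns the input unchanged. Standards are excluded from
  effect estimation and corrected with the cohort-derived effects; batch
  correction is per cohort. Derived traits are computed from % areas first
  and then run through the same log + correction chain, keeping the trait
  and peak scales coherent.
* **QC estimators**: standards error = 100·Var(standards)/Var(cohort) per
  peak (sample variances, n−1); replicate error = 100·(1 − Pearson r across
  pairs); CV = 100·SD/mean. QC runs on the batch-corrected log scale by
  default (flag for the percent scale). At ~70 standards a single peak's
  variance ratio has ≈17% sampling SD, so recovery of the injected
  technical fraction is assessed on the across-peak mean.

## Derived traits

Each peak contributes through its dominant structure only. The fifteen
default traits are feature sums: A2/A3/A4 (antennarity), G0–G4
(galactose count), S0–S3 (sialic-acid count, linkage-agnostic; linkage-
specific traits can be user-defined), F (any core fucose), B (bisecting
GlcNAc), HM (high-mannose). Three families partition the panel —
{A2,A3,A4,HM}, {G0..G4,HM}, {S0..S3,HM} — and each therefore sums to
100 ± 1e−6 per sample, a property the tests exploit. Annotations validate
that high-mannose peaks carry no galactose or sialic acid and that
galactoses never exceed antennae.

## Association layer

RINT uses the (rank − ½)/n convention with average ranks for ties
(missing values preserved in place); alternatives such as Blom offsets can
be configured by transforming externally. The glycan trait is the
regression **outcome**, the phenotype the predictor, both RINT-standardized
(binary phenotypes stay 0/1), covariates untransformed; OLS on complete
cases per pair, t-test p for the phenotype, DF = n − (predictors + 1).
Adjusted correlations residualize outcome (and quantitative predictor) on
the covariates and report the Pearson r of residuals with a t-test on
n − 2 − q DF. The sex-stratified age smoother is locally weighted linear
regression (tricube weights over the nearest `span` fraction of points,
default 0.75) on a fixed 50-point age grid with pointwise 95% CIs from the
local WLS variance; strata under 30 points are skipped.

Meta-analysis is inverse-variance fixed-effects with Normal (not t)
p-values, matching the standard `metagen(method="FE")` behavior; a single
available cohort passes through unchanged. BH adjustment is applied within
one family per analysis configuration per cohort, and one family for the
meta column (the family is configurable — published adjusted p-values
imply family sizes that are not always stated). No heterogeneity
statistics, random-effects models, or kinship adjustment.

## Mass matching

Residue monoisotopic masses (Hex 162.0528, HexNAc 203.0794, dHex 146.0579,
Neu5Ac 291.0954) live in a data table and are verified in tests against an
atomic-composition oracle to < 1e−3 Da. The 2-AB label plus sodium adduct
is a single opaque 143 Da constant, as used in GlycoMod-style searches —
deliberately not decomposed into label/adduct chemistry, so matching
reproduces that procedure exactly. Derivatized sialic acids shift by
+28.0313 Da (ethyl ester, α2,6) or −18.0106 Da (lactone, α2,3) relative to
underivatized Neu5Ac. Candidate search enumerates the bounded grid
(hex ≤ 12, hexnac ≤ 8, dhex ≤ 3, neuac ≤ 4 — covering the largest
structure in the default panels, F2A4G4S2) and returns hits within
tolerance sorted by |Δmass| then counts. Whether the tolerance applies to
the neutral or sodiated species is a convention choice; the labeled+adduct
mass defined above is used throughout.

## Problem sizes and determinism

All simulations are driven by `numpy.random.default_rng` seeds; identical
(config, seed) gives bit-identical outputs, and pipeline result CSVs carry
the config hash and seed in a header comment. The test suite's
study-scale checks use two cohorts of 900 samples (effect recovery,
100 replicates) and two cohorts of 300 samples (null FDR calibration,
100 replicates of the 135-pair grid) — sizes at which the checked
properties are stable while the whole suite stays fast; the full default
study (927 + 958 samples) runs in well under a minute on one CPU.

## Known limitations

* The default peak annotations and GU windows are plausible
  reconstructions, not the published supplementary panels; both are
  CSV-overridable and the pinned major transferrin structures are the only
  assignments taken from the main text.
* Location-only ComBat-style correction assumes batch effects shift but do
  not rescale log measurements; use `adjust_scale=True` if scale effects
  are suspected.
* Compositional closure couples traits: injected effects on large trait
  groups induce opposite-signed effects on complementary groups, and
  realized correlations for traits overshadowed by a large varying group
  are attenuated relative to their configured β.
* Binary phenotypes enter regression as 0/1 outcomes of a latent-Gaussian
  threshold; effects are injected on the latent scale, so realized
  point-biserial correlations with the observed binary are attenuated by
  the thresholding.
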