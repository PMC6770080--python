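# Methods

## Model and estimators

`tsmr` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics. Genetic variants serve as instrumental variables for an exposure
(here serum alpha-tocopherol, mg/L); under the instrumental-variable
assumptions — association with the exposure, independence from confounders,
and no effect on the outcome except through the exposure — the ratio of the
variant–outcome to the variant–exposure association estimates the causal
effect of the exposure.

For instrument *k*, let *E<sub>k</sub>* be the per-allele exposure effect and
*D<sub>k</sub>* the per-allele outcome effect with standard error
*σ<sub>Dk</sub>*. The per-SNP Wald ratio is *D<sub>k</sub>/E<sub>k</sub>* with
first-order delta-method standard error *σ<sub>Dk</sub>/|E<sub>k</sub>|*;
first-stage uncertainty in *E<sub>k</sub>* is ignored at this step. This is
deliberate: the fixed-effect inverse-variance-weighted (IVW) pool

    beta_IVW = Σ E_k D_k σ_Dk⁻² / Σ E_k² σ_Dk⁻²
    SE(beta_IVW) = sqrt(1 / Σ E_k² σ_Dk⁻²)

is then *exactly* the inverse-variance-weighted mean of the Wald ratios (the
two routes are asserted equal to 1e-12 in the test suite), and weights depend
only on the outcome-side variance. The price is the usual weak-instrument
attenuation when first-stage noise is non-negligible (quantified below). A
second-order delta method is out of scope.

Heterogeneity among the Wald ratios is measured by Cochran's Q with the
fixed IVW weights *w<sub>k</sub> = E<sub>k</sub>²/σ<sub>Dk</sub>²*, df = k−1,
I² = max(0, (Q−df)/Q) and the DerSimonian–Laird (DL) between-SNP variance
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). When the heterogeneity test rejects at
`het_alpha` (default 0.05, matching the published pattern of fixed models at
p_het = 0.15 and random models at p_het < 0.001), pooling switches to an
additive random-effects model with weights 1/(se<sub>k</sub>² + τ²). With
τ² = 0 the random model reduces exactly to the fixed one; its SE is never
smaller. A multiplicative (scaling) random-effects model would be a
reasonable alternative; the additive DL form is the standard IVW choice and
the only one implemented.

Confidence intervals are Wald intervals with z = Φ⁻¹(0.975) ≈ 1.959964 and
two-sided p-values come from the standard normal. Log-odds results are
exponentiated to odds ratios per 1 mg/L only at presentation time.

Instrument strength uses the first-stage F-statistic
F = ((n−k−1)/k)·R²/(1−R²), with R² computed from allele frequencies under
Hardy–Weinberg equilibrium and independence:
R² = Σ 2 p<sub>k</sub>(1−p<sub>k</sub>) E<sub>k</sub>² / Var(exposure).

## Harmonization

Exposure and outcome tables are aligned to a common effect allele before any
estimation. Non-palindromic variants align by allele letters, complementing
strands when needed; a letter swap negates the outcome beta and complements
its allele frequency. Palindromic variants (A/T, G/C) are strand-ambiguous:
under the default `infer_by_eaf` policy the interpretation whose aligned
effect-allele frequency falls on the same side of 0.5 as the exposure's is
chosen, and the variant is dropped whenever either frequency is missing or
lies within `eaf_ambiguity_band` (default 0.08) of 0.5. The default is
inference rather than dropping because the emulated instrument set retains a
G/C variant (rs964184, EAF 0.15, far from 0.5) that a blanket drop policy
would discard; `drop` is available for conservative use. Missing outcome EAF
on a palindromic SNP always drops the variant — assuming same-strand
reporting risks silently flipping an effect sign. Instrument selection keeps
associations with p strictly below `p_threshold` (default 5e-8).

## The synthetic-data generator

`synthetic_data.simulate_study` emulates the two-sample design at
summary-statistic level. Defaults are the emulated study's conditions: the
3-SNP instrument (per-allele effects 0.03, 0.03, 0.04 mg/L; EAFs 0.15, 0.21,
0.15; chromosomes 12, 19, 11), first-stage n = 7781, and a binary outcome
with 60,801 cases and 123,504 controls. For SNP *k* with EAF *p*:

* exposure beta ~ Normal(E_k, σ_Ek²), σ_Ek = exposure_sd/√(2p(1−p)·n_exposure);
* outcome beta ~ Normal(θ·E_k + α_k, σ_Dk²), σ_Dk = 1/√(2p(1−p)·n_eff),

where θ is the true causal effect, α_k an optional direct (horizontal
pleiotropy) effect, and n_eff the outcome sample size for an SD-standardized
continuous trait or n_cases·n_controls/(n_cases+n_controls) for a binary
trait on the log-odds scale. Reported SEs are the analytic σ values;
p-values follow from the two-sided normal test. One seeded generator is
shared per run: exposure betas are drawn first (in SNP order), then outcome
betas, so a seed fixes both tables.

**Exposure SD default (0.24 mg/L).** The published instrument table prints
first-stage SEs of 0.01 at two decimals alongside p-values of 8.2e-9 to
7.8e-12 — mutually inconsistent (beta 0.03 with SE 0.01 is z ≈ 3). Inverting
the p-values gives σ_E ≈ 0.0046–0.0058 for all three SNPs, which rounds to
the printed 0.01 and implies a phenotype SD of 0.23–0.26 mg/L at n = 7781
under Hardy–Weinberg scaling. The default 0.24 mg/L reproduces the published
first-stage z-scores; it was fixed from this inversion, not fitted to any
downstream result. At this default the 3-SNP instrument explains R² ≈ 1.6%
of exposure variance, F ≈ 43 — the same order as the published F = 48, whose
underlying phenotype variance was never stated.

**What the generator does not emulate.** No LD (the emulated instruments sit
on different chromosomes), no winner's-curse enrichment of the first-stage
effects, no individual-level genotypes, no sample overlap between the two
studies, and no allele-frequency drift between them (both tables report the
same EAF). Passing Monte-Carlo tests therefore demonstrate estimator
calibration under the assumed sampling model, not robustness to LD leakage,
selection bias or strand misreporting in real consortium data.

## Numerical choices

* I² is reported as 0 when Q = 0 (avoiding 0/0); p_het is reported as
  missing (not 1) when k = 1; negative DL τ² is truncated at 0.
* Strict inequality for instrument selection (p < threshold).
* Result tables are written at 10 significant digits and round-trip through
  the reader; simulated fixtures are written at 17 significant digits so the
  file-based pipeline is bit-identical to the in-memory one.
* Rounding to display precision (3 decimals, p-values shown as "<0.001")
  happens only in the rendered report, never in machine-readable output.
* Deterministic rsid-sorted ordering everywhere, so pooled results are
  independent of input row order.
* Synthetic pipeline configs re-select instruments at p < 1e-3 rather than
  5e-8: the generator re-draws first-stage betas with z ≈ 6, and the
  instruments are pre-selected by design, so a genome-wide re-check would
  randomly drop variants purely through simulation noise that a discovery
  GWAS would not re-impose.

## Monte-Carlo design

At the emulated sample sizes the per-replicate pooled SE is ≈ 0.16 on the
log-odds scale — roughly 3× the simulated true effect ln(1.05) ≈ 0.049. Two
consequences shape the test design:

1. **Coverage and size, not power.** The suite asserts 95% CI coverage
   within 95% ± 2% and type-I error within 5% ± 1.5% over 1000 replicates
   (Monte-Carlo SE ≈ 0.7 percentage points), which the estimator meets.
   Detecting θ = 0.049 in a single replicate is not expected at this noise
   level.
2. **Median recovery at two resolutions.** The Monte-Carlo SE of a
   1000-replicate median is ≈ 0.006 — larger than a 5% band around θ — so a
   "median within 5%" assertion at study scale would be a coin flip for any
   estimator. The suite instead asserts (a) the median is within 3
   Monte-Carlo SEs of θ at study scale, and (b) the median is within 5% of θ
   in a reduced-noise regime (outcome effective sample size ×100), where the
   band is resolvable and the only systematic deviation is weak-instrument
   attenuation. That attenuation — E[β̂]/θ ≈ ΣwE²/Σw(E²+σ_E²) ≈ 0.97 at the
   default exposure noise — is an expected property of ratio-based IVW, not
   an implementation artifact.

Pleiotropy sensitivity is tested by injecting a direct log-odds effect
α = 0.05 on the rs964184 analogue (a plausible magnitude for a lipid-locus
effect on coronary disease, comparable to the simulated causal signal
itself). Over 500 replicates the bias of the 3-SNP pool is directional in
sign(α·E_k) and excluding the variant reduces the median absolute error by
roughly two thirds.

## Known limitations

Only the ratio/IVW family is implemented — no MR-Egger, weighted median or
mode-based estimators, no Steiger filtering, no multivariable MR. There is
no LD clumping or proxy lookup; inputs are assumed independent. Multiple
outcomes are reported without multiplicity adjustment, matching per-outcome
reporting conventions. The first-order Wald SE understates uncertainty when
instruments are weak (F ≲ 10); the F-statistic block is reported precisely
so users can check this.
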