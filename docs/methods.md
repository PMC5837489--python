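# Methods

## Setting

`mrscore` implements a two-sample Mendelian randomization (MR) contrast:
per-allele associations of a set of *PCSK9* variants with an exposure
(LDL-C, mmol/L) come from one study population, per-allele log-odds
associations with disease outcomes (CHD, ischaemic stroke and its
subtypes) from others. Scaling each outcome effect by the variant's
exposure effect puts all variants on a common axis — log odds per
1 mmol/L lower LDL-C — on which outcomes can be compared.

## Effect-unit algebra

Published inputs arrive in mixed representations. The package converts
once, at load time, to a single in-memory convention:

* odds ratios → natural-log odds; OR-scale CI bounds are retained as
  published so that files stay visually comparable to printed tables;
* a 95% CI with no SE → SE = (ln U − ln L)/(2z) on the log-odds scale, or
  (U − L)/(2z) on a linear scale. The default z is the exact 97.5%
  normal quantile (1.959964); the packaged analysis uses z = 1.96 because
  the printed tables are 2-decimal rounded and that is the quantile that
  reproduces them. SEs are reconstructed from CIs rather than back-solved
  from p-values: printed p-values carry only order-of-magnitude
  precision;
* LDL effects in SD units → mmol/L via 1 SD = 1.0083 mmol/L (a pooled SD
  across lipid-consortium studies). The constant is taken as fixed; its
  per-study constituents were never published;
* harmonization orients every exposure/outcome pair to the
  **LDL-lowering** allele, keyed on the sign of the exposure effect (not
  on allele frequency). Flipping swaps alleles, complements the
  frequency, negates the effect and mirrors CI bounds; |β| and SE are
  invariant. Strand ambiguity is out of scope — palindromic (A/T, C/G)
  pairs only trigger a warning, as the packaged panel contains none.

Exposure records in the packaged fixtures store the signed per-allele
effect (−0.50 mmol/L for rs11591147-T), not the positive "reduction"
the tables print: the sign is what harmonization and the Wald ratio key
on, and the magnitude remains directly checkable.

## Estimators

The Wald ratio divides the outcome log odds and its SE by the magnitude
of the exposure effect. The SE is first order — exposure-side sampling
error is ignored. This is the convention that exactly reproduces the
published genetic-score CIs from the per-variant rows; a second-order
(Burgess-style delta) option would widen the CHD score CI by under 2% at
these instrument strengths and is deliberately not the default.

The genetic risk score is a fixed-effects inverse-variance-weighted
combination of the Wald ratios of LD-independent variants. Fixed-effects
meta-analysis across studies uses identical mathematics and is exposed
as a separate named stage. No random-effects model, MR-Egger, weighted
median or other pleiotropy-robust estimator is provided: the analysis
this package reproduces used IVW only, and adding estimators the
acceptance analysis never exercises would suggest validation that does
not exist.

Pooled p-values are two-sided normal; Q p-values are upper-tail
chi-square. For a single input Q = 0 with 0 df, and its p-value is
reported as 1 by convention.

## Heterogeneity and power

Outcome contrasts use the 1-df Q between two pooled estimates; scaling
both estimates by a common positive factor leaves Q unchanged, so
per-allele and per-mmol/L contrasts agree. Across k variants, Q against
the IVW mean has k−1 df; for k = 2 it is algebraically identical to the
1-df contrast, and the tests assert that identity numerically.

Power for a per-allele case-control test is the closed-form Wald
formula, with the *expected* SE computed from the effect-allele frequency
and the case/control counts under Hardy–Weinberg equilibrium and allele
counting. An observed-SE variant is available via an argument. The
opposite-sign rejection tail is ignored (it is < 10⁻⁸ at any relevant
design). With the ischaemic-stroke sample (EAF 1.5%, 10 307 cases,
19 326 controls) and a CHD-sized alternative (OR 0.77) at α = 0.008 this
gives 84.9% power, consistent with the "about 80%" the source analysis
reported; using the observed IS standard error instead gives materially
less, which is why the expected-SE form is the default.

The adjusted significance level α = 0.008 is applied as a strict
inequality (p < α); p = α exactly is not significant.

## LD and instrument independence

D′ and r² are computed from two-locus haplotype frequencies by the
standard normalizations (D′ = |D|/D_max with D_max the margin-limited
bound on |D| of matching sign). Both are clamped to [0, 1] against
floating-point rounding; monomorphic loci raise an error rather than
return a value.

Score membership follows the rule "exclude if D′ with the index variant
is strictly greater than 0.6"; a tie at exactly 0.6 is retained. Because
the numeric pairwise D′/r² values for the published panel exist only in
an unavailable supplement, the packaged LD fixture carries qualitative
exceeds-threshold flags; the filter accepts either flags or numbers, and
the pipeline *refuses* to score a panel with no LD source at all rather
than silently assume independence — dropping four of the six variants is
the analysis's central correction and must never silently not happen.

## Synthetic cohorts

The generator draws, per individual, two haplotypes over m biallelic
variants (optionally with pairwise LD applied as a first-order Markov
chain along adjacent variants — the only sampler generally consistent
with pairwise-specified haplotype tables; marginals are validated), an
LDL-C value `mean + Σ genotype·effect + N(0, σ)`, and Bernoulli outcomes
with logit `baseline + θ_trait · (genetic mmol/L lowered)`. Outcomes
depend on the *genetic* exposure component only, so θ is exactly the
estimand the score targets and recovery tests have clean truth; real
exposures feed environmental variance into outcomes too, which this
default deliberately omits.

Defaults mirror the study conditions: two independent variants with
lowering-allele frequencies 0.015 and 0.965 and effects −0.50 and
−0.09 mmol/L per allele; θ_CHD = −0.51 (the log of the 0.60 score OR),
θ_IS = 0; n = 100 000; LDL mean 3.6 mmol/L and noise SD 1.0 mmol/L
(≈ the population SD, since these variants explain little variance);
baseline log-odds −1.0 per trait (≈27% cases, of the order of the
case fraction in the stroke consortium sample). All randomness flows
through one seeded generator; a fixed seed reproduces cohorts and
written files byte-for-byte.

Summary-statistic extraction is closed-form: the exposure effect is the
simple-regression slope of LDL on allele count with its textbook SE; the
outcome effect is the log cross-product ratio of the 2×2
lowering-allele × case/control table with SE √(Σ 1/cell), continuity
correction +0.5 on empty cells (warned), monomorphic variants dropped
(warned). Allele-count ORs coincide with genotypic logistic ORs to first
order under Hardy–Weinberg; the calibration tests (type-I error within
Monte-Carlo error of α at n = 1500, empirical power within 5 points of
the closed form at n = 4000) quantify how good that approximation is at
realistic sizes. Case/control imbalance arises from the baseline
log-odds; no case-control ascertainment or sampling design is modelled,
matching the summary-statistics abstraction. No population
stratification, relatedness, imputation error or genotyping error is
simulated — passing recovery tests say nothing about robustness to
those.

Simulation-based tests use desk-scale problem sizes chosen once: 2000
null replicates for type-I calibration, 1000 for empirical power, 200
replicates of the default n = 100 000 cohort for CI coverage
(≥ 90% required) and for the heterogeneity-test power comparison
against the noncentral-chi-square closed form.

## Numerical conventions and known drift

* Display rounding is decimal half-up to 2 decimals on the OR scale,
  applied only at the report edge; the JSON report and all tests use
  unrounded values.
* P-values below 10⁻⁴ are displayed in one-significant-digit scientific
  notation; stored unrounded.
* Recomputation from 2-decimal rounded published inputs cannot reproduce
  every printed value exactly. Observed drift, documented rather than
  tuned away: the across-variant heterogeneity p for CHD recomputes to
  0.034 (printed 0.02) and for IS to 0.48 (printed 0.56); the
  cardioembolic and large-artery subtype score ORs recompute to 1.53 and
  1.17 (printed 1.51 and 1.16); and the rs2479409 CHD row's rounded CI
  (0.95–0.99) implies p = 0.004 although the printed p is 0.01 — the one
  row whose significance status at α = 0.008 cannot be reproduced from
  its CI. No constant is adjusted to force agreement.

## Limitations

The package handles the two-sample summary-statistics design only: no
individual-level MR, no VCF/GWAS-VCF ingestion, no reference-panel LD
estimation, no unphased-data EM haplotyping, and no pleiotropy-robust
estimators. The Wald-ratio SE ignores exposure uncertainty, which is
anti-conservative for weak instruments; with the instruments here
(F-statistics in the hundreds) the effect is negligible, but the package
should not be pointed at weak-instrument panels without adding the
second-order term.
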