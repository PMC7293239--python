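# Methods

## CHIP calling model

A variant call is retained as a CHIP driver only if it passes every gate
below; gates are evaluated in a fixed order and *all* failures are
reported, so filter attribution is auditable.

1. **VAF floor** (`vaf_min`, default 0.01). The discovery limit of the
   assay. The classic CHIP definition uses 0.02 (`vaf_chip_classic`);
   calling below it is what the contamination machinery makes safe.
2. **Germline gate** (`vaf_germline_max`, default 0.35). Variants above
   VAF 0.35 usually reflect germline heterozygosity rather than a clone.
   Eight genes are exempt (DNMT3A, TET2, ASXL1, PPM1D, TP53, JAK2, SF3B1,
   SRSF2) because genuine drivers in them can reach high clonal fractions.
3. **Caller confidence**: SNVs require TLOD ≥ 6.3 (MuTect2-style tumor
   log-odds), indels QSI_NT ≥ 30 (Strelka-style quality); "below" is
   strict, so a score exactly at the threshold passes. A missing score on
   the relevant variant type fails in strict mode (default) — unscored
   calls should not slip through silently; set
   `strict_missing_quality=False` to relax.
4. **Minimum alternate reads**: max(4, smallest k with
   P[Bin(depth, c/f) ≥ k] < α), where c is the sample's cross-individual
   contamination fraction, α = `contamination_alpha` (default 0.01) and
   f = `contamination_rate_factor` (default 3).
5. **Contamination exceedance**: the one-sided exact binomial test of the
   observed alternate count against Bin(depth, c/f) must reject at α.
   (Gate 4 is this test's quantile plus the floor of 4; both reasons are
   reported separately for auditability.)
6. **Driver whitelist**: per-gene modes `truncating_only`,
   `hotspots_only`, `truncating_and_hotspots`, `any_nonsynonymous`;
   hotspots are protein positions ("R882") or exact changes ("V617F").
   Genes without an entry are never drivers. The shipped defaults cover
   the eight exempt genes and are a best-effort reconstruction; they are
   user-replaceable via YAML, and any real deployment should review them.

**Contamination model.** Contaminating reads derive from a second
individual's DNA at fraction c. At a site where the contaminator is
heterozygous, half its reads carry the alternate allele, and the
contaminator does not always carry the allele at all, so a single
effective per-read alternate rate of c/3 is used. This is a tractable,
deliberately conservative stand-in: for a *somatic* driver position the
true contaminant alternate rate is far lower (a random individual almost
never carries the same somatic mutation), so the gate errs toward
filtering. The factor is configurable.

A sample with measurable ULP-WGS tumor fraction is flagged (default) or
dropped (`tumor_fraction_policy="drop"`); flag-only is the default because
removing such samples is a sensitivity analysis, not part of the primary
call.

## Force-calling and clonal tracking

Given a mutation list and pileup allele counts from another sample of the
same patient, a mutation is *detected* when the one-sided exact binomial
test of its alternate count against rate `base_error + c/3` rejects at α
(defaults: base error 1e-3 per read, α = 0.01). Detection is therefore
depth-driven and can sit below the discovery VAF floor. Sites without a
pileup row or with zero depth are *uncovered*; a patient whose sites are
all uncovered at a timepoint is excluded from the clonal-relation
denominator. A patient is "clonally related" when at least one mutation is
detected at both the transplant-product and diagnosis timepoints;
`fold_change` is the later/earlier VAF ratio, undefined when the earlier
VAF is zero.

## Survival and association statistics

All estimators are implemented directly (lifelines and R's survival/cmprsk
serve only as independent oracles in the tests):

* **Kaplan-Meier**: product-limit estimator; Greenwood variance
  S(t)² Σ d/(n(n−d)); 95% bands on the log(−log S) scale; the median is
  the earliest event time with S ≤ 0.5 and is flagged undefined when the
  curve never crosses it.
* **Log-rank**: k-sample observed-minus-expected chi-square with the
  hypergeometric variance (tie factor d(n−d)/(n−1)); pairwise tests are
  reported unadjusted.
* **Stratified Cox**: Newton-Raphson with step-halving on the sum of
  per-stratum log partial likelihoods, Efron tie correction, convergence
  at gradient max-norm < 1e-8 (≤ 50 iterations). Strata without events
  contribute nothing. Wald CIs exp(b ± 1.96 se). A flat likelihood (e.g. a
  covariate constant within every stratum) converges at b = 0 with an
  infinite SE rather than erroring; |b| > 15 triggers a monotone-
  likelihood (separation) warning; a singular information matrix with a
  non-zero gradient raises an error naming the offending column. The
  default stratification is the full cross-classification age group x ISS
  x prior treatment lines (≤ 72 strata at n = 629, about 9 subjects each —
  sparse but consistent for a conditional likelihood; the tests verify
  recovery and coverage at exactly this sparsity).
* **Competing risks**: Aalen-Johansen cumulative incidence per cause; the
  identity EFS(t) + Σ_k CIF_k(t) = 1 holds to machine precision by
  construction (shared risk sets, telescoping product). Gray's k-sample
  test uses Gray's subdistribution risk sets
  R_j(t) = Y_j(t)(1−F_kj(t−))/S_j(t−) with ρ = 0 weighting, and a
  log-rank-style hypergeometric variance on those weighted risk sets.
  This reduces *exactly* to the log-rank test when no competing events
  exist. With censoring and competing events the variance is first-order
  (Gray's full estimator, which also tracks the estimation error of the
  weights, is not reproduced); against R's cmprsk on a 150-subject
  two-group fixture the statistic agrees to ~1%, and a 400-replicate null
  simulation keeps the 5%-level rejection rate inside its binomial band.
* **Fisher exact** (two-sided): sum of hypergeometric point probabilities
  ≤ the observed one (with the customary 1+1e-7 slack); degenerate margins
  give p = 1.
* **Wilcoxon rank-sum**: exact null distribution (dynamic program over
  rank subsets) when min(n, m) ≤ 10 with no ties; otherwise the normal
  approximation with tie correction and continuity correction.
* **Ordered trend**: the "trend test for singly-ordered tables" is
  implemented as the Jonckheere-Terpstra statistic (sum of pairwise
  Mann-Whitney counts across ordered groups) with its tie-corrected normal
  approximation, one-sided. This is a deliberate substitution for the
  ambiguous "Kruskal-Wallis trend test" label: Kruskal-Wallis itself has
  no direction, and JT is the standard ordered-alternative analogue.

Endpoints: OS is time from transplant to death from any cause; PFS to
progression or death, whichever first; TMN is analyzed as cause 1 with
death as the competing absorbing cause 2, both measured from transplant.

## Synthetic cohort generator

The generator emulates the *observed* cohort of a CHIP-ASCT study — the
tables a sequencing-and-filtering pipeline would deliver — not the latent
biology beneath it:

* **Demographics** (defaults): 629 patients; age bins 20-29 … 70-79 with
  weights (2, 16, 89, 251, 252, 19)/629; CHIP prevalence per bin
  (0, 2/16, 7/89, 48/251, 70/252, 9/19), giving 136/629 = 21.6% expected
  overall; ISS 353/170/106; prior lines 434/118/44/33; 57% first-line IMiD
  maintenance; 36% smokers with ~1% missing smoking status.
* **Mutations**: carriers draw 1-3 mutated genes
  (p = 0.853/0.125/0.022) without replacement from a spectrum led by
  DNMT3A (0.38) then TET2, TP53, ASXL1, PPM1D, JAK2, SF3B1, SRSF2.
  Emitted mutation types conform to the shipped driver rules (e.g. DNMT3A
  truncating or R882 missense; TET2/ASXL1/PPM1D truncating) so that
  planted truth and whitelist semantics agree. Per-patient noise calls
  (Poisson, mean 0.4) — synonymous calls, VAF≈0.5 germline-like variants
  in non-whitelist genes, sub-threshold artifacts, low-TLOD calls — are
  planted so specificity is earned by the rules, not by absence of
  temptation.
* **VAF spectrum**: clone VAFs follow a log-normal truncated to
  [0.01, 0.5]. Calibration is against observed summaries: σ ≈ 3.013 from
  requiring the planted patient-level P(max clone ≥ 0.10) = 0.176 under
  the gene-count mixture, and μ ≈ −9.635 from requiring the
  detection-weighted median — the median among mutations that clear the
  0.01 cutoff under binomial sampling at 978x — to be 0.027. The printed
  trio (median 0.027, P(max ≥ 0.10) = 0.176, P(max ≥ 0.02) ≈ 0.65) is
  over-determined for this two-parameter family once detection is
  modeled: with the median pinned, the achievable tail saturates near
  0.16 and P(≥ 0.02) near 0.64. The median, being the primary reported
  quantity, is matched exactly; the achieved tails sit 1-3 percentage
  points below the printed ones.
* **Read support**: depth ~ Poisson(978); each carrier clone's
  (VAF, depth, alt) triple is drawn jointly conditioned on the measured
  fraction clearing the discovery cutoff — a cohort's reported carriers
  are by definition those the assay could report, so the truth set is the
  detection-conditioned law (of which the calibrated weighted density is
  the VAF marginal). Sub-threshold clonal hematopoiesis is real but
  outside the emulated study's truth; setting `vaf_lo=0` recovers an
  unconditioned generator.
* **Contamination**: uniform on [0.01, 0.08] per sample. For carriers the
  upper limit is lowered to the largest c at which the smallest planted
  clone still clears the contamination gate in expectation with a 2-SD
  margin — the same detection-conditioning logic: a reported clone
  necessarily cleared its own sample's contamination floor, so the
  observed joint (VAF, c) distribution is conditioned on detection.
* **Event times**: exponential cause-specific hazards with baseline
  log-hazard shifts by age bin (+0.18/bin), ISS (+0.15/level) and prior
  lines (+0.10/line) — heterogeneity the stratified Cox must absorb.
  Covariate effects are the configured HRs (CHIP 1.34 on OS, 1.45 on PFS;
  maintenance 0.65 and 0.47; CHIP x maintenance 0.51 on PFS only).
  Baseline rates: death ln2/7.1 y⁻¹, PFS ln2/2.5 y⁻¹, TMN 0.006 y⁻¹ with
  maintenance HR 3 and CHIP HR 1 (TMN risk tracks maintenance exposure,
  not CHIP). OS and PFS are drawn comonotonically (shared uniform), which
  preserves both exponential marginals exactly while guaranteeing
  PFS ≤ OS; the configuration validator enforces the hazard-dominance
  condition this requires. Administrative censoring is uniform on
  [8, 16.6] years.
* **Two-timepoint data** (`simulate_tmn_pair`): 10 TMN patients, 8 with a
  driver planted at VAF 0.005-0.02 at transplant (often below the 0.01
  discovery floor) and expanded 15-50x at diagnosis, 2 with the driver
  only at diagnosis; pileups at 2000x with counts emitted as
  round(VAF x depth) so the constructed 8/10 split is exact by design.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: site-specific error profiles and
orientation-bias artifacts (noise classes are stylized and deterministic-
ally filterable); clonal dynamics over time; per-gene VAF differences (a
shared spectrum is assumed); informative censoring; covariate-dependent
contamination; the true driver-rule table of any particular study (the
shipped whitelist is a reconstruction).

**Parameter-recovery semantics.** Recovery of the configured HRs is
evaluated by fitting the models on the *true* CHIP covariate carried in
the clinical table; this isolates the survival stack. The caller's
agreement with the planted status is quantified separately
(sensitivity/specificity), and the pipeline's end-to-end run uses the
called status, as a real analysis would.

## Problem sizes and numerical choices

* Parameter recovery (test suite): 1200 replicate cohorts of n = 629 for
  CI coverage (binomial MC noise ~0.007), with the mean-recovery check on
  the first 100 replicates; Wald coverage at this stratification sits
  near 0.94.
* The acceptance script averages the per-cohort retained-driver median
  VAF over 50 default cohorts.
* Newton-Raphson: start at 0, step-halving on likelihood decrease,
  tolerance 1e-8, cap 50 iterations; linear predictors clipped at ±200
  before exponentiation.
* Exact binomial quantiles are found from scipy's ppf then corrected by
  local scan, so boundary cases (tail exactly at α) follow the strict
  inequality in the gate definitions.
* Ages above 79 are folded into the 70-79 bin (the oldest printed bin) for
  stratification.

## Known limitations

* The Gray-test variance is the first-order hypergeometric form (exact
  only without competing events); p-values under heavy censoring with
  strong group imbalance may deviate by a few percent from cmprsk's.
* The driver whitelist ships with eight genes; variants in other CHIP
  genes are not called unless the user supplies rules.
* The exact Wilcoxon path requires tie-free data; tied small samples use
  the normal approximation.
* Fine-Gray subdistribution *regression* is out of scope (only Gray's
  test is provided); so are time-varying covariates and frailty terms.
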