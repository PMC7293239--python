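# chipcall

Detection of clonal hematopoiesis of indeterminate potential (CHIP) from
somatic variant call tables, and analysis of its impact on survival and
therapy-related myeloid neoplasm (TMN) risk in a transplant cohort.

## The problem

CHIP is the presence of leukemia-associated somatic driver mutations
(most often in *DNMT3A*, *TET2*, *TP53*, *ASXL1*, *PPM1D*) in the blood of
people without a hematologic malignancy. In multiple-myeloma patients it
can be measured in the mobilized stem-cell product collected before
autologous stem cell transplantation (ASCT), and its presence is associated
with worse overall survival (OS) and progression-free survival (PFS) —
effects that interact with post-transplant immunomodulatory-drug (IMiD)
maintenance therapy.

Calling CHIP from deep targeted sequencing (~1000x) is mostly a filtering
problem. Small clones (variant allele fraction, VAF, down to 0.01) must be
separated from cross-sample contamination, sequencing artifacts and
germline polymorphisms. This package implements that rule engine and the
downstream cohort statistics:

* **Variant filtering** — a VAF floor of 0.01; exclusion of likely germline
  variants (VAF > 0.35) outside an eight-gene exemption list; caller
  confidence gates (SNV TLOD ≥ 6.3, indel QSI_NT ≥ 30); and a
  contamination-aware minimum alternate-read count: the smallest k with
  P[Binomial(depth, c/3) ≥ k] < α for single-sample contamination c,
  floored at 4 reads. A 2% clone is therefore *not* callable in a sample
  with ~3% contamination, but is in a clean one.
* **Driver classification** — a whitelist keyed on gene, mutation type and
  protein position (e.g. *DNMT3A* truncating or R882, *JAK2* V617F only,
  *TP53* any non-synonymous), shipped as replaceable YAML.
* **Force-calling** — querying the read support for a fixed mutation list
  in a second sample from the same patient (e.g. at TMN diagnosis), with
  an exact binomial detection test against error + contamination; this
  recovers clones below the discovery threshold.
* **Outcome statistics, written from first principles** — Kaplan-Meier
  with Greenwood variance and log-log CIs; k-sample and pairwise log-rank
  tests; stratified Cox regression (Newton-Raphson on the stratified
  partial likelihood, Efron tie correction, Wald inference); the
  Aalen-Johansen cumulative-incidence estimator with death as a competing
  absorbing event and Gray's test on subdistribution hazards; Fisher exact,
  Wilcoxon rank-sum, and a Jonckheere-Terpstra ordered-trend test.
* **A calibrated synthetic cohort generator** — age-dependent CHIP
  prevalence (21.6% overall, 47% at ages 70-79), a DNMT3A-led gene
  spectrum, a truncated log-normal VAF distribution (median 0.027), read
  counts emitted binomially at ~978x, and exponential cause-specific event
  times with proportional-hazards effects (CHIP: OS HR 1.34, PFS 1.45;
  maintenance: OS 0.65, PFS 0.47; CHIP x maintenance on PFS 0.51).

## Worked example

```bash
python analysis/01_simulate_cohort.py   # writes results/cohort/
python analysis/02_call_chip.py         # caller + mutational spectrum
python analysis/03_outcomes.py          # Cox / KM / competing risks
python analysis/04_clonal_tracking.py   # two-timepoint force-calling
```

With the default configuration (seed 1) this prints:

```
CHIP-positive: 136/629 (21.6%)
median retained-driver VAF: 0.0257
...
--- stratified Cox, OS ---
       term    coef     hr     se    lci    uci       z      p
       chip  0.2994 1.3490 0.1294 1.0469 1.7384  2.3139 0.0207
maintenance -0.3982 0.6716 0.1074 0.5441 0.8289 -3.7077 0.0002
--- stratified Cox, PFS ---
            term    coef     hr     se    lci    uci       z      p
            chip  0.4006 1.4928 0.1695 1.0707 2.0811  2.3631 0.0181
     maintenance -0.7836 0.4567 0.1097 0.3684 0.5663 -7.1449 0.0000
chip:maintenance -0.7486 0.4730 0.2426 0.2940 0.7610 -3.0855 0.0020
gray_tmn_by_maintenance: chi2 = 15.522, p = 0.000
gray_tmn_by_chip: chi2 = 1.346, p = 0.246
...
patients with a detectable mutation at both timepoints: 8/10
```

Reading the output: the caller finds CHIP in 21.6% of the simulated
patients; the stratified Cox models (strata: age group x ISS stage x prior
treatment lines) recover hazard ratios near the configured truths — CHIP
worsens OS (HR ≈ 1.35) and PFS (≈ 1.49), maintenance is protective, and
the negative interaction means maintenance abrogates the PFS harm of CHIP.
Gray's test attributes TMN incidence to maintenance exposure, not to CHIP,
and force-calling shows 8 of 10 TMN patients carried their driver, often
below VAF 0.01, already at transplant.

The same steps are available as a CLI: `chipcall simulate`, `chipcall
call`, `chipcall track`, `chipcall run-all` (see `chipcall --help`).

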