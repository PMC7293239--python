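"""Synthetic cohort generator.

Emulates a transplant cohort of multiple-myeloma patients with CHIP
(clonal hematopoiesis) measured in the stem-cell product at transplant:

* age drawn from the cohort's printed age-bin distribution, with CHIP
  prevalence per age bin (overall expectation 136/629 = 21.6%, rising to
  9/19 = 47% in the 70-79 bin);
* for carriers, 1-3 mutated genes (85.3% single-gene) sampled from a gene
  frequency spectrum with DNMT3A modal, then TET2 and TP53;
* clone allele fractions from a log-normal truncated to [0.01, 0.5] whose
  location/scale are calibrated so the per-mutation median is 0.027 and the
  probability that a carrier's largest clone reaches VAF 0.10 is 17.6%
  (the tail constraint is applied at the patient level through the
  gene-count mixture; at the per-mutation level the two constraints are
  jointly infeasible for this family);
* read support emitted as binomial draws at a Poisson read depth
  (mean 978x), with caller confidence scores, plus a configurable rate of
  non-driver "noise" variants (synonymous calls, germline-like polymorphisms
  at VAF ~0.5 in non-whitelist genes, sub-threshold artifacts, low-TLOD
  calls) that a correct filter chain must remove;
* cross-sample contamination uniform on [0.01, 0.08]; carriers' samples are
  drawn from the subset of that range compatible with their smallest clone
  clearing the contamination gate in expectation (a clone reported by a
  study necessarily cleared its own sample's contamination floor, so the
  observed joint (VAF, contamination) distribution is detection-conditioned);
* exponential cause-specific event times with proportional covariate
  effects: CHIP on OS (HR 1.34) and PFS (1.45), first-line IMiD maintenance
  on OS (0.65) and PFS (0.47) with a CHIP x maintenance interaction on PFS
  (0.51); a small TMN hazard competing with death (maintenance raises it);
  administrative censoring. OS and PFS draws are comonotone (shared uniform)
  so progression never postdates death.

The generator's ground truth (true CHIP status per patient, configured
hazard ratios) is emitted alongside the tables, so the caller and the
survival stack can each be scored against what was planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

from . import io as cio
from .classifier import FilterThresholds, SampleContext
from .errors import ConfigurationError
from .tracking import MutationId

AGE_BINS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]
AGE_BIN_COUNTS = (2, 16, 89, 251, 252, 19)
CHIP_BY_AGE_COUNTS = (0, 2, 7, 48, 70, 9)

#: gene -> (relative frequency, chromosome, base position)
GENE_TABLE = {
    "DNMT3A": (0.38, "2", 25457000),
    "TET2":   (0.17, "4", 106155000),
    "TP53":   (0.13, "17", 7572000),
    "ASXL1":  (0.09, "20", 31015000),
    "PPM1D":  (0.08, "17", 58700000),
    "JAK2":   (0.06, "9", 5073770),
    "SF3B1":  (0.05, "2", 198266000),
    "SRSF2":  (0.04, "17", 74732000),
}

#: per-gene mutation templates conforming to the default driver rules:
#: (variant_class, protein_change, weight)
GENE_MUTATIONS = {
    "DNMT3A": [("nonsense", "p.W305*", 0.30), ("frameshift_del", "p.V716fs", 0.25),
               ("splice_site", None, 0.10), ("missense", "p.R882H", 0.25),
               ("missense", "p.R882C", 0.10)],
    "TET2":   [("nonsense", "p.Q742*", 0.45), ("frameshift_ins", "p.H1380fs", 0.35),
               ("splice_site", None, 0.20)],
    "TP53":   [("missense", "p.R175H", 0.35), ("missense", "p.R248Q", 0.30),
               ("missense", "p.R273H", 0.26), ("nonsense", "p.R196*", 0.09)],
    "ASXL1":  [("frameshift_ins", "p.G646fs", 0.60), ("nonsense", "p.R693*", 0.40)],
    "PPM1D":  [("nonsense", "p.R552*", 0.55), ("frameshift_del", "p.L450fs", 0.45)],
    "JAK2":   [("missense", "p.V617F", 1.0)],
    "SF3B1":  [("missense", "p.K700E", 1.0)],
    "SRSF2":  [("missense", "p.P95H", 1.0)],
}

OTHER_GENES = ["TTN", "MUC16", "OBSCN", "FLG"]  # never whitelisted


@lru_cache(maxsize=None)
def calibrate_vaf_lognormal(median: float = 0.027,
                            patient_tail: float = 0.176,
                            tail_at: float = 0.10,
                            lo: float = 0.01, hi: float = 0.5,
                            n_gene_probs: tuple = (0.853, 0.125, 0.022),
                            mean_depth: float = 978.0) -> tuple[float, float]:
    """Location/scale (mu, sigma) of the planted clone-VAF log-normal,
    truncated to [lo, hi], calibrated against the *observed* spectrum.

    The reported VAF summaries of a cohort study describe the mutations the
    study retained, so the calibration targets are applied to the
    detection-weighted density f(v) * w(v), where w(v) is the first-order
    probability that a clone of allele fraction v clears the discovery VAF
    cutoff under binomial read sampling at the study depth:
    w(v) = P[Bin(depth, v) >= ceil(lo * depth)].

    The scale sigma is set by the planted-spectrum calibration (truncated
    median = ``median`` and a planted upper tail such that P(a carrier's
    largest clone >= ``tail_at``) = ``patient_tail`` under the gene-count
    mixture; at the per-mutation level the printed median/tail pair is
    infeasible for this family). The location mu is then re-solved under
    the detection weighting so that the *retained* median matches the
    printed one; with the detection filter in the model, no (mu, sigma)
    can match median and tail simultaneously, and the median is the
    primary reported observable.
    """
    depth = int(round(mean_depth))
    k_min = int(np.ceil(lo * depth))
    a, b, m = np.log(lo), np.log(hi), np.log(median)

    def mixture(q):
        return sum(p * (1 - (1 - q) ** (k + 1))
                   for k, p in enumerate(n_gene_probs))

    q = optimize.brentq(lambda x: mixture(x) - patient_tail, 1e-6, 0.999)

    # --- sigma: unweighted (planted-spectrum) calibration ----------------
    def solve_t(s):
        da, db = (a - m) / s, (b - m) / s
        g = lambda t: norm.cdf(t) - 0.5 * (norm.cdf(t + da) + norm.cdf(t + db))
        ts = np.linspace(-20, 20, 2001)
        vals = np.array([g(t) for t in ts])
        idx = np.where(np.diff(np.sign(vals)) != 0)[0]
        best = max(idx, key=lambda j: abs(vals[j]) + abs(vals[j + 1]))
        return optimize.brentq(g, ts[best], ts[best + 1])

    def planted_tail(s):
        mu_ = m - solve_t(s) * s
        za, zb = (a - mu_) / s, (b - mu_) / s
        zh = (np.log(tail_at) - mu_) / s
        return (norm.sf(zh) - norm.sf(zb)) / (norm.sf(za) - norm.sf(zb))

    sigma = optimize.brentq(lambda s: planted_tail(s) - q, 0.5, 8.0)

    # --- mu: detection-weighted median condition -------------------------
    grid = np.exp(np.linspace(a, b, 2000))
    logg = np.log(grid)
    w = stats.binom.sf(k_min - 1, depth, grid)

    def weighted_cdf_at(mu_, v):
        dens = norm.pdf((logg - mu_) / sigma) * w  # d(log v) measure
        total = np.trapezoid(dens, logg)
        mask = grid <= v
        return np.trapezoid(dens[mask], logg[mask]) / total

    mu = optimize.brentq(lambda mu_: weighted_cdf_at(mu_, median) - 0.5,
                         m - 12 * sigma, m + 12 * sigma)
    return float(mu), float(sigma)


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_patients: int = 629
    seed: int = 0

    age_bin_counts: tuple = AGE_BIN_COUNTS
    chip_by_age: tuple = tuple(c / n for c, n in
                               zip(CHIP_BY_AGE_COUNTS, AGE_BIN_COUNTS))
    iss_probs: tuple = (353 / 629, 170 / 629, 106 / 629)
    prior_lines_probs: tuple = (434 / 629, 118 / 629, 44 / 629, 33 / 629)
    p_male: float = 361 / 629
    p_smoking: float = 228 / 622        # among non-missing
    p_smoking_missing: float = 7 / 629
    p_maintenance: float = 0.57

    gene_freqs: dict = field(default_factory=lambda: {
        g: f for g, (f, _, _) in GENE_TABLE.items()})
    n_gene_probs: tuple = (0.853, 0.125, 0.022)

    vaf_median: float = 0.027
    vaf_patient_tail: float = 0.176
    vaf_tail_at: float = 0.10
    vaf_lo: float = 0.01
    vaf_hi: float = 0.5

    mean_depth: float = 978.0
    contamination_lo: float = 0.01
    contamination_hi: float = 0.08
    carrier_margin_sd: float = 2.0      # detection-conditioning safety margin
    p_tumor_fraction: float = 49 / 629
    tumor_fraction_range: tuple = (0.03, 0.054)
    noise_rate: float = 0.4             # Poisson mean of junk variants/patient

    lam_death: float = float(np.log(2) / 7.1)   # cohort median OS 7.1 y
    lam_pfs: float = float(np.log(2) / 2.5)     # cohort median PFS 2.5 y
    lam_tmn: float = 0.006
    hr_chip_os: float = 1.34
    hr_chip_pfs: float = 1.45
    hr_maint_os: float = 0.65
    hr_maint_pfs: float = 0.47
    hr_chip_maint_pfs: float = 0.51
    hr_maint_tmn: float = 3.0
    hr_chip_tmn: float = 1.0
    log_age_effect: float = 0.18        # baseline log-hazard shift per age bin
    log_iss_effect: float = 0.15        # ... per ISS level
    log_lines_effect: float = 0.10      # ... per prior line
    censor_lo: float = 8.0
    censor_hi: float = 16.6

    def __post_init__(self):
        probs = list(self.chip_by_age) + list(self.iss_probs) + \
            list(self.prior_lines_probs) + list(self.n_gene_probs) + \
            [self.p_male, self.p_smoking, self.p_maintenance]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if min(self.lam_death, self.lam_pfs, self.lam_tmn) <= 0:
            raise ConfigurationError("hazards must be positive")
        # PFS hazard must dominate the OS hazard for every covariate pattern
        # (comonotone coupling guarantees progression <= death only then)
        worst = (self.lam_pfs * self.hr_chip_pfs * self.hr_maint_pfs *
                 self.hr_chip_maint_pfs) / (self.lam_death * self.hr_chip_os *
                                            self.hr_maint_os)
        if worst <= 1.0:
            raise ConfigurationError(
                "PFS hazard must exceed OS hazard for all covariate patterns")

    @property
    def vaf_params(self) -> tuple[float, float]:
        return calibrate_vaf_lognormal(
            self.vaf_median, self.vaf_patient_tail, self.vaf_tail_at,
            self.vaf_lo, self.vaf_hi, self.n_gene_probs, self.mean_depth)


@dataclass
class SyntheticCohort:
    clinical: cio.ClinicalTable
    variants: cio.VariantTable
    contexts: list[SampleContext]
    truth: dict
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_clinical(self.clinical, outdir / "clinical.csv")
        cio.write_maf(self.variants, outdir / "variants.maf.tsv")
        cio.write_contexts(self.contexts, outdir / "contexts.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _sample_truncated_lognormal(rng, mu, sigma, lo, hi, size):
    zlo = norm.cdf((np.log(lo) - mu) / sigma)
    zhi = norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(zlo, zhi, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


@lru_cache(maxsize=None)
def _contamination_threshold(depth: int, contamination: float,
                             alpha: float, factor: float) -> int:
    """Smallest alt count clearing the contamination-exceedance test."""
    if contamination == 0:
        return 1
    p = contamination / factor
    k = int(stats.binom.ppf(1 - alpha, depth, p))
    while k > 0 and stats.binom.sf(k - 1, depth, p) < alpha:
        k -= 1
    while stats.binom.sf(k, depth, p) >= alpha:
        k += 1
    return k + 1


def _max_compatible_contamination(vaf_min_clone: float, cfg: SimConfig,
                                  thresholds: FilterThresholds) -> float:
    """Largest contamination in [lo, hi] at which the smallest clone still
    clears the contamination gate in expectation, with a safety margin of
    ``carrier_margin_sd`` binomial standard deviations."""
    depth = int(round(cfg.mean_depth))
    expected_alt = vaf_min_clone * depth
    margin = cfg.carrier_margin_sd * np.sqrt(
        depth * vaf_min_clone * (1 - vaf_min_clone))
    for c in np.arange(cfg.contamination_hi, cfg.contamination_lo - 1e-12,
                       -0.005):
        c = round(float(c), 6)
        k = _contamination_threshold(depth, c,
                                     thresholds.contamination_alpha,
                                     thresholds.contamination_rate_factor)
        if expected_alt >= max(k, thresholds.alt_reads_floor) + margin:
            return c
    return cfg.contamination_lo


def _pick(rng, options_weights):
    opts = [o[:-1] for o in options_weights]
    w = np.array([o[-1] for o in options_weights], dtype=float)
    idx = rng.choice(len(opts), p=w / w.sum())
    return opts[idx]


_BASES = np.array(list("ACGT"))


def _alleles(rng, variant_class):
    if variant_class == "frameshift_del":
        return "".join(rng.choice(_BASES, 2)), "-"
    if variant_class == "frameshift_ins":
        return "-", str(rng.choice(_BASES))
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def _emit_variant(rng, cfg, sample_id, gene, vaf, variant_class,
                  protein_change):
    _, chrom, base = GENE_TABLE.get(gene, (0, "1", 1_000_000))
    depth = max(int(rng.poisson(cfg.mean_depth)), 30)
    alt_count = int(rng.binomial(depth, vaf))
    ref, alt = _alleles(rng, variant_class)
    is_indel = "-" in (ref, alt)
    return {
        "sample_id": sample_id, "gene": gene, "chrom": chrom,
        "pos": int(base + rng.integers(0, 5000)), "ref": ref, "alt": alt,
        "variant_class": variant_class, "protein_change": protein_change,
        "alt_count": alt_count, "ref_count": depth - alt_count,
        "vaf": alt_count / depth if depth else 0.0,
        "tlod": np.nan if is_indel else float(rng.uniform(20, 300)),
        "qsi_nt": float(rng.uniform(40, 300)) if is_indel else np.nan,
    }


def _draw_clone(rng, cfg, mu, sigma):
    """Draw a reportable clone: (true VAF, depth, alt count) conditioned on
    the measured allele fraction clearing the discovery cutoff.

    The cohort's CHIP carriers are, by definition, patients whose clone the
    assay reports; sub-threshold clonal hematopoiesis exists but is outside
    the study's truth set, so the generator samples the detection-
    conditioned joint distribution directly (whose per-mutation density is
    the weighted density the calibration targets).
    """
    for _ in range(200):
        v = float(_sample_truncated_lognormal(rng, mu, sigma, cfg.vaf_lo,
                                              cfg.vaf_hi, 1)[0])
        depth = max(int(rng.poisson(cfg.mean_depth)), 30)
        alt = int(rng.binomial(depth, v))
        if alt / depth >= cfg.vaf_lo:
            return v, depth, alt
    # unreachable in practice: acceptance probability is ~0.5 even at the
    # lower truncation bound
    return v, depth, max(alt, int(np.ceil(cfg.vaf_lo * depth)))


def _emit_noise(rng, cfg, sample_id):
    """A variant that the filter chain must reject (deterministically, so
    specificity is attributable to the rules rather than luck)."""
    kind = rng.choice(4, p=[0.3, 0.3, 0.2, 0.2])
    genes = list(GENE_TABLE)
    if kind == 0:    # synonymous call in a whitelist gene
        gene = str(rng.choice(genes))
        row = _emit_variant(rng, cfg, sample_id, gene,
                            float(rng.uniform(0.01, 0.25)), "synonymous", None)
    elif kind == 1:  # germline-like polymorphism in a non-whitelist gene
        gene = str(rng.choice(OTHER_GENES))
        row = _emit_variant(rng, cfg, sample_id, gene,
                            float(rng.uniform(0.42, 0.58)), "missense",
                            "p.A100V")
    elif kind == 2:  # sub-threshold artifact (non-driver class)
        gene = str(rng.choice(OTHER_GENES + genes))
        row = _emit_variant(rng, cfg, sample_id, gene,
                            float(rng.uniform(0.002, 0.008)), "synonymous",
                            None)
    else:            # driver-looking call with a failing TLOD
        gene = str(rng.choice(genes))
        vclass, pchange = _pick(rng, GENE_MUTATIONS[gene])
        row = _emit_variant(rng, cfg, sample_id, gene,
                            float(rng.uniform(0.02, 0.10)), vclass, pchange)
        if np.isnan(row["qsi_nt"]):
            row["tlod"] = float(rng.uniform(1.0, 6.0))
        else:
            row["qsi_nt"] = float(rng.uniform(1.0, 25.0))
    return row


def simulate_cohort(cfg: SimConfig | None = None,
                    thresholds: FilterThresholds | None = None
                    ) -> SyntheticCohort:
    """Generate one synthetic cohort (clinical table + variant calls +
    QC contexts + ground truth)."""
    cfg = cfg or SimConfig()
    thresholds = thresholds or FilterThresholds()
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = cfg.vaf_params
    genes = list(cfg.gene_freqs)
    gene_p = np.array([cfg.gene_freqs[g] for g in genes], dtype=float)
    gene_p /= gene_p.sum()
    age_p = np.array(cfg.age_bin_counts, dtype=float)
    age_p /= age_p.sum()

    clin_rows, var_rows, contexts = [], [], []
    truth_patients = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        bin_idx = int(rng.choice(len(AGE_BINS), p=age_p))
        age = int(rng.integers(20 + 10 * bin_idx, 30 + 10 * bin_idx))
        chip = bool(rng.random() < cfg.chip_by_age[bin_idx])
        sex = "M" if rng.random() < cfg.p_male else "F"
        iss = int(rng.choice([1, 2, 3], p=np.asarray(cfg.iss_probs)))
        lines_idx = int(rng.choice(4, p=np.asarray(cfg.prior_lines_probs)))
        prior_lines = ["0", "1", "2", "3+"][lines_idx]
        maint = bool(rng.random() < cfg.p_maintenance)
        if rng.random() < cfg.p_smoking_missing:
            smoking = np.nan
        else:
            smoking = bool(rng.random() < cfg.p_smoking)

        clones = []
        if chip:
            n_genes = int(rng.choice([1, 2, 3], p=np.asarray(cfg.n_gene_probs)))
            chosen = rng.choice(genes, size=n_genes, replace=False, p=gene_p)
            for g in chosen:
                v, depth, alt = _draw_clone(rng, cfg, mu, sigma)
                vclass, pchange = _pick(rng, GENE_MUTATIONS[str(g)])
                clones.append({"gene": str(g), "vaf": v,
                               "depth": depth, "alt_count": alt,
                               "variant_class": vclass,
                               "protein_change": pchange})
        if clones:
            c_hi = _max_compatible_contamination(
                min(c["vaf"] for c in clones), cfg, thresholds)
            contamination = float(rng.uniform(cfg.contamination_lo, c_hi)) \
                if c_hi > cfg.contamination_lo else cfg.contamination_lo
        else:
            contamination = float(rng.uniform(cfg.contamination_lo,
                                              cfg.contamination_hi))
        tumor_fraction = None
        if rng.random() < cfg.p_tumor_fraction:
            tumor_fraction = float(rng.uniform(*cfg.tumor_fraction_range))
        contexts.append(SampleContext(
            sample_id=pid, contamination=contamination,
            tumor_fraction=tumor_fraction, mean_depth=cfg.mean_depth))

        for clone in clones:
            _, chrom, base = GENE_TABLE[clone["gene"]]
            ref, alt_base = _alleles(rng, clone["variant_class"])
            is_indel = "-" in (ref, alt_base)
            var_rows.append({
                "sample_id": pid, "gene": clone["gene"], "chrom": chrom,
                "pos": int(base + rng.integers(0, 5000)),
                "ref": ref, "alt": alt_base,
                "variant_class": clone["variant_class"],
                "protein_change": clone["protein_change"],
                "alt_count": clone["alt_count"],
                "ref_count": clone["depth"] - clone["alt_count"],
                "vaf": clone["alt_count"] / clone["depth"],
                "tlod": np.nan if is_indel else float(rng.uniform(20, 300)),
                "qsi_nt": float(rng.uniform(40, 300)) if is_indel else np.nan,
            })
        for _ in range(rng.poisson(cfg.noise_rate)):
            var_rows.append(_emit_noise(rng, cfg, pid))

        # --- event times -------------------------------------------------
        stratum_mult = float(np.exp(
            cfg.log_age_effect * (bin_idx - 3)
            + cfg.log_iss_effect * (iss - 2)
            + cfg.log_lines_effect * lines_idx))
        h_os = cfg.lam_death * stratum_mult * \
            cfg.hr_chip_os ** chip * cfg.hr_maint_os ** maint
        h_pfs = cfg.lam_pfs * stratum_mult * \
            cfg.hr_chip_pfs ** chip * cfg.hr_maint_pfs ** maint * \
            cfg.hr_chip_maint_pfs ** (chip and maint)
        u1 = rng.random()
        t_death = -np.log(u1) / h_os
        t_pfs = -np.log(u1) / h_pfs            # comonotone: t_pfs <= t_death
        h_tmn = cfg.lam_tmn * cfg.hr_maint_tmn ** maint * \
            cfg.hr_chip_tmn ** chip
        t_tmn = -np.log(rng.random()) / h_tmn
        censor = float(rng.uniform(cfg.censor_lo, cfg.censor_hi))
        os_time = min(t_death, censor)
        os_event = int(t_death <= censor)
        pfs_time = min(t_pfs, censor)
        pfs_event = int(t_pfs <= censor)
        tmn_time = min(t_tmn, os_time)
        tmn_event = int(t_tmn < os_time)

        clin_rows.append({
            "patient_id": pid, "age": age, "age_group": AGE_BINS[bin_idx],
            "sex": sex, "iss": iss, "prior_lines": prior_lines,
            "chip": chip, "n_chip_genes": len({c["gene"] for c in clones}),
            "maintenance": maint, "smoking": smoking,
            "os_time": round(os_time, 6), "os_event": os_event,
            "pfs_time": round(pfs_time, 6), "pfs_event": pfs_event,
            "tmn_time": round(tmn_time, 6), "tmn_event": tmn_event,
        })
        truth_patients[pid] = {"chip": chip, "clones": clones}

    clinical = cio.ClinicalTable(df=pd.DataFrame(clin_rows))
    variants = cio.VariantTable(
        df=pd.DataFrame(var_rows, columns=cio.VARIANT_COLUMNS), dialect="maf")
    truth = {
        "patients": truth_patients,
        "hr": {"chip_os": cfg.hr_chip_os, "chip_pfs": cfg.hr_chip_pfs,
               "maint_os": cfg.hr_maint_os, "maint_pfs": cfg.hr_maint_pfs,
               "chip_maint_pfs": cfg.hr_chip_maint_pfs},
        "vaf_lognormal": {"mu": mu, "sigma": sigma},
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
    }
    return SyntheticCohort(clinical=clinical, variants=variants,
                           contexts=contexts, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# two-timepoint data for clonal tracking
# ---------------------------------------------------------------------------

@dataclass
class TmnPairData:
    """Synthetic transplant-product / TMN-diagnosis sample pairs."""

    mutations_by_patient: dict[str, list[MutationId]]
    pileups: list[pd.DataFrame]             # [timepoint1, timepoint2]
    contexts_by_patient: dict[str, list[SampleContext]]
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(self.pileups, start=1):
            cio.write_pileup(p, outdir / f"pileup_t{i}.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def simulate_tmn_pair(cfg: SimConfig | None = None, n_patients: int = 10,
                      n_shared: int = 8, pileup_depth: int = 2000,
                      contamination: float = 0.002) -> TmnPairData:
    """Two-timepoint force-calling data: ``n_shared`` of ``n_patients`` TMN
    patients carry a driver present (often below the 0.01 discovery
    threshold) at transplant that has expanded at TMN diagnosis; the rest
    have the driver only at diagnosis.

    Pileup alt counts are deterministic (``round(vaf * depth)``) so the
    constructed shared/unshared split is exact by design.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed + 777)
    muts: dict[str, list[MutationId]] = {}
    ctxs: dict[str, list[SampleContext]] = {}
    rows1, rows2 = [], []
    truth = {"patients": {}}
    genes = ["TP53", "TP53", "DNMT3A", "TET2", "PPM1D"]  # TP53-heavy, as at TMN
    for i in range(n_patients):
        pid = f"T{i + 1:02d}"
        shared = i < n_shared
        gene = genes[i % len(genes)]
        _, chrom, base = GENE_TABLE[gene]
        pos = int(base + rng.integers(0, 5000))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        m = MutationId(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)
        vaf1 = float(rng.uniform(0.005, 0.02)) if shared else 0.0
        vaf2 = float(min(vaf1 * rng.uniform(15, 50), 0.45)) if shared \
            else float(rng.uniform(0.10, 0.40))
        s1, s2 = f"{pid}_asct", f"{pid}_tmn"
        rows1.append({"sample_id": s1, "chrom": chrom, "pos": pos,
                      "ref": ref, "alt": alt,
                      "alt_count": int(round(vaf1 * pileup_depth)),
                      "depth": pileup_depth})
        rows2.append({"sample_id": s2, "chrom": chrom, "pos": pos,
                      "ref": ref, "alt": alt,
                      "alt_count": int(round(vaf2 * pileup_depth)),
                      "depth": pileup_depth})
        muts[pid] = [m]
        ctxs[pid] = [
            SampleContext(sample_id=s1, contamination=contamination,
                          mean_depth=pileup_depth),
            SampleContext(sample_id=s2, contamination=contamination,
                          mean_depth=pileup_depth),
        ]
        truth["patients"][pid] = {"shared": shared, "gene": gene,
                                  "vaf_asct": vaf1, "vaf_tmn": vaf2}
    truth["n_shared"] = n_shared
    truth["n_patients"] = n_patients
    return TmnPairData(
        mutations_by_patient=muts,
        pileups=[pd.DataFrame(rows1), pd.DataFrame(rows2)],
        contexts_by_patient=ctxs, truth=truth)
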