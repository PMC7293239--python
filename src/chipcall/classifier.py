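"""CHIP-calling rule engine.

A somatic variant observed in a stem-cell product is retained as a CHIP
driver only if it clears, in order:

1. a minimum allele fraction (``vaf_min``, default 0.01);
2. a germline gate: VAF above 0.35 usually indicates a germline
   polymorphism and is excluded, except in eight genes whose drivers are
   known to reach high clonal fractions (DNMT3A, TET2, ASXL1, PPM1D, TP53,
   JAK2, SF3B1, SRSF2);
3. caller-confidence gates: SNVs need TLOD >= 6.3, indels QSI_NT >= 30;
4. a minimum alternate-read count that is a function of read depth and the
   sample's cross-individual contamination, floored at 4 reads;
5. a contamination-exceedance test: the alternate-read support must exceed,
   at significance ``contamination_alpha``, what a contaminating second
   individual could explain. Contaminating reads enter at rate *c*; at a
   site where the contaminator is heterozygous half of those carry the
   alternate allele, and the contaminator does not always carry it, so an
   effective per-read alternate rate of c/3 is used (configurable via
   ``contamination_rate_factor``);
6. a driver whitelist keyed on gene, mutation type and protein position:
   genes absent from the rules are never drivers.

Every gate is evaluated (no short-circuiting) so the full set of failure
reasons is reported for filter attribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ChipcallError, ConfigurationError, ValidationError

TRUNCATING_CLASSES = {"nonsense", "frameshift_ins", "frameshift_del", "splice_site"}
NONSYNONYMOUS_CLASSES = TRUNCATING_CLASSES | {"missense", "inframe_indel"}

#: genes exempt from the VAF > 0.35 germline exclusion
GERMLINE_VAF_EXEMPT = {
    "DNMT3A", "TET2", "ASXL1", "PPM1D", "TP53", "JAK2", "SF3B1", "SRSF2",
}

FILTER_REASONS = (
    "below_vaf_min", "above_germline_vaf", "fails_tlod", "fails_qsi",
    "insufficient_alt_reads", "within_contamination", "not_driver",
    "tumor_contaminated_sample",
)


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observation in one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    protein_change: Optional[str] = None
    alt_count: int = 0
    ref_count: int = 0
    tlod: Optional[float] = None
    qsi_nt: Optional[float] = None

    def __post_init__(self):
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValidationError("read counts must be non-negative")
        if self.depth < 1:
            raise ValidationError("total depth must be >= 1")

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth

    @property
    def is_indel(self) -> bool:
        # MAF encodes indels with '-' alleles; VCF with length change.
        return ("-" in (self.ref, self.alt)) or (len(self.ref) != len(self.alt))

    @property
    def is_snv(self) -> bool:
        return not self.is_indel


@dataclass(frozen=True)
class SampleContext:
    """Per-sample QC: contamination fraction, optional ULP-WGS tumor
    fraction, mean sequencing depth."""

    sample_id: str
    contamination: float
    tumor_fraction: Optional[float] = None
    mean_depth: float = 978.0

    def __post_init__(self):
        if not 0 <= self.contamination < 0.5:
            raise ValidationError(
                f"contamination {self.contamination} outside [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.tumor_fraction is not None and not 0 <= self.tumor_fraction <= 1:
            raise ValidationError("tumor_fraction outside [0, 1]")


@dataclass(frozen=True)
class FilterThresholds:
    vaf_min: float = 0.01
    vaf_chip_classic: float = 0.02
    vaf_germline_max: float = 0.35
    tlod_min: float = 6.3
    qsi_nt_min: float = 30.0
    alt_reads_floor: int = 4
    contamination_alpha: float = 0.01
    contamination_rate_factor: float = 3.0  # effective contaminant rate c/3
    strict_missing_quality: bool = True     # absent score on relevant type fails

    def __post_init__(self):
        if not 0 < self.vaf_min < self.vaf_germline_max < 1:
            raise ValidationError("need 0 < vaf_min < vaf_germline_max < 1")
        if self.alt_reads_floor < 1:
            raise ValidationError("alt_reads_floor must be >= 1")


@dataclass
class DriverRule:
    """Whitelist entry for one gene.

    mode:
      * ``truncating_only`` — nonsense/frameshift/splice-site calls;
      * ``hotspots_only`` — nonsynonymous calls at listed protein positions;
      * ``truncating_and_hotspots`` — union of the two;
      * ``any_nonsynonymous`` — any protein-altering call.
    Hotspots are protein positions ("R882") or exact changes ("V617F").
    """

    gene: str
    mode: str
    hotspots: list[str] = field(default_factory=list)
    germline_vaf_exempt: bool = False

    MODES = ("truncating_only", "truncating_and_hotspots", "hotspots_only",
             "any_nonsynonymous")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValidationError(f"unknown driver-rule mode {self.mode!r}")


_PROTEIN_RE = re.compile(r"^(?:p\.)?([A-Za-z*]+?)(\d+)(.*)$")


def _parse_protein(change: str):
    m = _PROTEIN_RE.match(change.strip())
    if not m:
        return None
    ref_aa, pos, rest = m.groups()
    return ref_aa.upper(), int(pos), rest


def hotspot_matches(protein_change: Optional[str], hotspot: str) -> bool:
    """True if a protein change hits a hotspot spec.

    "R882" matches any change at R882 (R882H, R882C...); "V617F" only the
    exact substitution. Position boundaries are respected ("R88" does not
    match R882H).
    """
    if not protein_change:
        return False
    obs = _parse_protein(protein_change)
    spot = _parse_protein(hotspot)
    if obs is None or spot is None:
        return False
    if obs[0] != spot[0] or obs[1] != spot[1]:
        return False
    return spot[2] == "" or obs[2].upper() == spot[2].upper()


class DriverRules:
    """Gene-keyed whitelist of driver rules (whitelist semantics: a gene
    with no entry is never a driver)."""

    def __init__(self, rules: Iterable[DriverRule]):
        self._rules: dict[str, DriverRule] = {}
        for r in rules:
            if r.gene in self._rules:
                raise ValidationError(f"duplicate rule for gene {r.gene}")
            self._rules[r.gene] = r

    def __contains__(self, gene: str) -> bool:
        return gene in self._rules

    def __getitem__(self, gene: str) -> DriverRule:
        return self._rules[gene]

    def genes(self) -> list[str]:
        return sorted(self._rules)

    def is_exempt(self, gene: str) -> bool:
        if gene in self._rules:
            return self._rules[gene].germline_vaf_exempt
        return gene in GERMLINE_VAF_EXEMPT

    def is_driver(self, v: VariantCall) -> bool:
        rule = self._rules.get(v.gene)
        if rule is None:
            return False
        if v.variant_class not in NONSYNONYMOUS_CLASSES:
            return False
        truncating = v.variant_class in TRUNCATING_CLASSES
        at_hotspot = any(hotspot_matches(v.protein_change, h)
                         for h in rule.hotspots)
        if rule.mode == "any_nonsynonymous":
            return True
        if rule.mode == "truncating_only":
            return truncating
        if rule.mode == "hotspots_only":
            return at_hotspot
        return truncating or at_hotspot  # truncating_and_hotspots

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {g: {"mode": r.mode, "hotspots": list(r.hotspots),
                    "germline_vaf_exempt": r.germline_vaf_exempt}
                for g, r in sorted(self._rules.items())}

    @classmethod
    def from_dict(cls, data: Mapping) -> "DriverRules":
        return cls(DriverRule(gene=g, mode=spec["mode"],
                              hotspots=list(spec.get("hotspots", [])),
                              germline_vaf_exempt=bool(spec.get(
                                  "germline_vaf_exempt",
                                  g in GERMLINE_VAF_EXEMPT)))
                   for g, spec in data.items())

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DriverRules":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_driver_rules() -> DriverRules:
    """Reconstruction of the driver whitelist for the commonly mutated CHIP
    genes; user-replaceable via YAML."""
    mk = lambda g, m, h=(): DriverRule(gene=g, mode=m, hotspots=list(h),
                                       germline_vaf_exempt=g in GERMLINE_VAF_EXEMPT)
    return DriverRules([
        mk("DNMT3A", "truncating_and_hotspots", ["R882"]),
        mk("TET2", "truncating_only"),
        mk("ASXL1", "truncating_only"),
        mk("PPM1D", "truncating_only"),
        mk("TP53", "any_nonsynonymous"),
        mk("JAK2", "hotspots_only", ["V617F"]),
        mk("SF3B1", "hotspots_only", ["K700E", "K666"]),
        mk("SRSF2", "hotspots_only", ["P95"]),
    ])


@dataclass(frozen=True)
class ChipCall:
    """Verdict for one variant: retained driver, or filtered with reasons."""

    variant: VariantCall
    status: str                # "retained_driver" | "filtered"
    reasons: tuple[str, ...]   # empty iff retained_driver
    tumor_flagged: bool = False

    def __post_init__(self):
        if (self.status == "retained_driver") != (len(self.reasons) == 0):
            raise ValidationError(
                "status must be retained_driver iff reasons is empty")


def min_alt_reads(depth: int, contamination: float,
                  thresholds: FilterThresholds | None = None) -> int:
    """Minimum alternate reads needed to call a variant at this depth and
    contamination.

    The smallest k such that P[Binomial(depth, c/3) >= k] < alpha — the
    support needed to reject "all alternate reads are contaminant-derived"
    — floored at 4 reads.
    """
    thresholds = thresholds or FilterThresholds()
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if not 0 <= contamination < 0.5:
        raise ValidationError(
            f"contamination {contamination} outside [0, 0.5)")
    return max(thresholds.alt_reads_floor,
               _contamination_quantile(depth, contamination, thresholds))


def _contamination_quantile(depth: int, contamination: float,
                            thresholds: FilterThresholds) -> int:
    """Smallest k with P[Bin(depth, c/f) >= k] < alpha (k=1 when c=0)."""
    if contamination == 0:
        return 1
    p = contamination / thresholds.contamination_rate_factor
    alpha = thresholds.contamination_alpha
    # start near the 1-alpha quantile, then scan to the exact boundary
    k = int(stats.binom.ppf(1 - alpha, depth, p))
    while k > 0 and stats.binom.sf(k - 1, depth, p) < alpha:
        k -= 1
    while stats.binom.sf(k, depth, p) >= alpha:
        k += 1
    return k + 1


def exceeds_contamination(alt_count: int, depth: int, contamination: float,
                          thresholds: FilterThresholds) -> bool:
    """One-sided exact binomial test: does the alternate-read support exceed
    what contamination alone explains?"""
    if contamination == 0:
        return alt_count >= 1
    p = contamination / thresholds.contamination_rate_factor
    return stats.binom.sf(alt_count - 1, depth, p) < thresholds.contamination_alpha


def passes_quality(v: VariantCall,
                   thresholds: FilterThresholds | None = None
                   ) -> tuple[bool, Optional[str]]:
    """Caller-confidence gate. SNVs are judged on TLOD (fail strictly below
    6.3), indels on QSI_NT (fail strictly below 30). A missing score on the
    relevant variant type fails in strict mode (the default)."""
    thresholds = thresholds or FilterThresholds()
    if v.is_indel:
        if v.qsi_nt is None:
            return (not thresholds.strict_missing_quality,
                    "fails_qsi" if thresholds.strict_missing_quality else None)
        if v.qsi_nt < thresholds.qsi_nt_min:
            return False, "fails_qsi"
        return True, None
    if v.tlod is None:
        return (not thresholds.strict_missing_quality,
                "fails_tlod" if thresholds.strict_missing_quality else None)
    if v.tlod < thresholds.tlod_min:
        return False, "fails_tlod"
    return True, None


def classify_variant(v: VariantCall, ctx: SampleContext, rules: DriverRules,
                     thresholds: FilterThresholds | None = None) -> ChipCall:
    """Run one variant through every gate; reasons accumulate in gate order
    and are never short-circuited."""
    thresholds = thresholds or FilterThresholds()
    if ctx.sample_id != v.sample_id:
        raise ConfigurationError(
            f"context sample {ctx.sample_id!r} != variant sample "
            f"{v.sample_id!r}")
    reasons: list[str] = []
    if v.vaf < thresholds.vaf_min:
        reasons.append("below_vaf_min")
    if v.vaf > thresholds.vaf_germline_max and not rules.is_exempt(v.gene):
        reasons.append("above_germline_vaf")
    ok, why = passes_quality(v, thresholds)
    if not ok:
        reasons.append(why)
    if v.alt_count < min_alt_reads(v.depth, ctx.contamination, thresholds):
        reasons.append("insufficient_alt_reads")
    if not exceeds_contamination(v.alt_count, v.depth, ctx.contamination,
                                 thresholds):
        reasons.append("within_contamination")
    if not rules.is_driver(v):
        reasons.append("not_driver")
    status = "retained_driver" if not reasons else "filtered"
    return ChipCall(variant=v, status=status, reasons=tuple(reasons))


@dataclass
class ChipCallSet:
    """Output of :func:`call_chip`: per-variant verdicts plus per-sample
    CHIP status."""

    calls: list[ChipCall]
    per_sample: pd.DataFrame  # sample_id, chip, n_drivers, n_genes, max_vaf, tumor_flagged
    tumor_flagged_samples: list[str]

    @property
    def retained(self) -> list[ChipCall]:
        return [c for c in self.calls if c.status == "retained_driver"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            v = c.variant
            rows.append({
                "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom,
                "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "variant_class": v.variant_class,
                "protein_change": v.protein_change, "vaf": v.vaf,
                "alt_count": v.alt_count, "ref_count": v.ref_count,
                "status": c.status, "reasons": ";".join(c.reasons),
                "tumor_flagged": c.tumor_flagged,
            })
        return pd.DataFrame(rows)


def call_chip(variants, contexts: Sequence[SampleContext],
              rules: DriverRules | None = None,
              thresholds: FilterThresholds | None = None,
              tumor_fraction_policy: str = "flag",
              tumor_fraction_cutoff: float = 0.0) -> ChipCallSet:
    """Classify every variant and derive per-sample CHIP status.

    A sample is CHIP-positive iff it has at least one retained driver.
    Samples whose ULP-WGS tumor fraction exceeds ``tumor_fraction_cutoff``
    are flagged; with ``tumor_fraction_policy="drop"`` their variants are
    additionally filtered (reason ``tumor_contaminated_sample``) and the
    samples excluded from the per-sample table.

    ``variants`` may be a :class:`~chipcall.io.VariantTable` or an iterable
    of :class:`VariantCall`.
    """
    if tumor_fraction_policy not in ("flag", "drop"):
        raise ConfigurationError(
            f"unknown tumor_fraction_policy {tumor_fraction_policy!r}")
    thresholds = thresholds or FilterThresholds()
    rules = rules or default_driver_rules()
    ctx_by_sample = {c.sample_id: c for c in contexts}
    if hasattr(variants, "iter_calls"):
        variants = list(variants.iter_calls())
    else:
        variants = list(variants)

    flagged = sorted({
        c.sample_id for c in contexts
        if c.tumor_fraction is not None
        and c.tumor_fraction > tumor_fraction_cutoff})
    flagged_set = set(flagged)

    calls: list[ChipCall] = []
    for v in variants:
        ctx = ctx_by_sample.get(v.sample_id)
        if ctx is None:
            raise ConfigurationError(
                f"variant in sample {v.sample_id!r} has no QC context")
        call = classify_variant(v, ctx, rules, thresholds)
        tflag = v.sample_id in flagged_set
        if tflag and tumor_fraction_policy == "drop":
            call = ChipCall(variant=v, status="filtered",
                            reasons=call.reasons + ("tumor_contaminated_sample",),
                            tumor_flagged=True)
        elif tflag:
            call = replace(call, tumor_flagged=True)
        calls.append(call)

    sample_ids = [c.sample_id for c in contexts]
    if tumor_fraction_policy == "drop":
        sample_ids = [s for s in sample_ids if s not in flagged_set]
    per = {s: {"sample_id": s, "chip": False, "n_drivers": 0,
               "genes": set(), "max_vaf": np.nan,
               "tumor_flagged": s in flagged_set}
           for s in sample_ids}
    for c in calls:
        if c.status != "retained_driver":
            continue
        s = c.variant.sample_id
        if s not in per:  # dropped tumor-contaminated sample
            continue
        rec = per[s]
        rec["chip"] = True
        rec["n_drivers"] += 1
        rec["genes"].add(c.variant.gene)
        v = c.variant.vaf
        rec["max_vaf"] = v if np.isnan(rec["max_vaf"]) else max(rec["max_vaf"], v)
    per_sample = pd.DataFrame([
        {"sample_id": r["sample_id"], "chip": r["chip"],
         "n_drivers": r["n_drivers"], "n_genes": len(r["genes"]),
         "max_vaf": r["max_vaf"], "tumor_flagged": r["tumor_flagged"]}
        for r in per.values()])
    return ChipCallSet(calls=calls, per_sample=per_sample,
                       tumor_flagged_samples=flagged)


@dataclass
class CohortSummary:
    """Cohort-level mutation-spectrum summary."""

    n_patients: int
    n_chip_patients: int
    prevalence: float
    gene_patient_counts: pd.Series      # patients with >= 1 retained call per gene
    genes_per_patient: pd.Series        # distinct mutated genes per CHIP patient
    max_vaf_per_patient: pd.Series
    median_vaf: float                   # over retained driver calls
    comutation: pd.DataFrame            # patients x genes, 0/1

    @property
    def modal_gene(self) -> Optional[str]:
        if self.gene_patient_counts.empty:
            return None
        return self.gene_patient_counts.idxmax()

    def multi_gene_fraction(self) -> float:
        """Fraction of CHIP patients with mutations in >= 2 distinct genes."""
        if self.n_chip_patients == 0:
            return float("nan")
        return float((self.genes_per_patient >= 2).sum()) / self.n_chip_patients

    def vaf_ge_fraction(self, cutoff: float) -> float:
        """Fraction of CHIP patients whose largest clone has VAF >= cutoff."""
        if self.n_chip_patients == 0:
            return float("nan")
        return float((self.max_vaf_per_patient >= cutoff).sum()) / self.n_chip_patients


def summarize_cohort(callset: ChipCallSet) -> CohortSummary:
    """Mutation-spectrum summaries over the retained driver calls."""
    per = callset.per_sample
    n = len(per)
    n_chip = int(per["chip"].sum())
    retained = callset.retained
    vafs = np.array([c.variant.vaf for c in retained])
    pairs = pd.DataFrame(
        [{"sample_id": c.variant.sample_id, "gene": c.variant.gene}
         for c in retained])
    if pairs.empty:
        gene_counts = pd.Series(dtype=int)
        comut = pd.DataFrame(index=pd.Index([], name="sample_id"))
    else:
        comut = (pairs.assign(v=1)
                 .pivot_table(index="sample_id", columns="gene", values="v",
                              aggfunc="max", fill_value=0))
        gene_counts = comut.sum(axis=0).sort_values(ascending=False)
    chip_rows = per[per["chip"]]
    return CohortSummary(
        n_patients=n,
        n_chip_patients=n_chip,
        prevalence=n_chip / n if n else float("nan"),
        gene_patient_counts=gene_counts,
        genes_per_patient=chip_rows.set_index("sample_id")["n_genes"],
        max_vaf_per_patient=chip_rows.set_index("sample_id")["max_vaf"],
        median_vaf=float(np.median(vafs)) if len(vafs) else float("nan"),
        comutation=comut,
    )
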