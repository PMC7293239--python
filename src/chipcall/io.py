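"""Readers/writers for the tabular formats the pipeline touches.

Dialects handled here:

* MAF-style TSV of per-sample somatic variant calls (Hugo_Symbol,
  Start_Position, t_ref_count/t_alt_count, ...), the shape most somatic
  callers' annotation steps emit;
* a minimal VCF 4.x with per-sample ``AD`` allelic depths and gene /
  classification tags in ``INFO``;
* a clinical cohort CSV (covariates plus OS/PFS/TMN event times);
* pileup allele-count TSVs used for force-calling;
* per-sample QC context TSVs (contamination, tumor fraction, depth).

Coordinates are 1-based inclusive throughout (MAF/VCF convention). ``.`` or
an empty field means missing. Rows violating an invariant are rejected with
row-indexed diagnostics rather than aborting the whole read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .classifier import SampleContext, VariantCall

VARIANT_CLASSES = {
    "missense", "nonsense", "frameshift_ins", "frameshift_del",
    "splice_site", "inframe_indel", "synonymous", "other",
}

#: MAF Variant_Classification values mapped onto the closed vocabulary.
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "missense",
    "Frame_Shift_Ins": "frameshift_ins",
    "Frame_Shift_Del": "frameshift_del",
    "Splice_Site": "splice_site",
    "In_Frame_Ins": "inframe_indel",
    "In_Frame_Del": "inframe_indel",
    "Silent": "synonymous",
}

MAF_MANDATORY = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "t_ref_count", "t_alt_count",
]
MAF_OPTIONAL = ["Tumor_Sample_Barcode", "Protein_Change", "TLOD", "QSI_NT"]

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "protein_change", "alt_count", "ref_count", "vaf", "tlod", "qsi_nt",
]

CLINICAL_REQUIRED = [
    "patient_id", "age", "sex", "iss", "prior_lines", "maintenance",
    "os_time", "os_event", "pfs_time", "pfs_event", "tmn_time", "tmn_event",
]

AGE_BINS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]


@dataclass
class RowDiagnostic:
    """One rejected/flagged input row."""
    line: int               # 1-based line number in the source file
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: [{self.field}] {self.message}"


@dataclass
class VariantTable:
    """Validated somatic variant observations, one row per call."""

    df: pd.DataFrame
    dialect: str = "maf"
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def iter_calls(self) -> Iterable[VariantCall]:
        for row in self.df.itertuples(index=False):
            yield VariantCall(
                sample_id=row.sample_id, gene=row.gene, chrom=str(row.chrom),
                pos=int(row.pos), ref=row.ref, alt=row.alt,
                variant_class=row.variant_class,
                protein_change=None if pd.isna(row.protein_change) else row.protein_change,
                alt_count=int(row.alt_count), ref_count=int(row.ref_count),
                tlod=None if pd.isna(row.tlod) else float(row.tlod),
                qsi_nt=None if pd.isna(row.qsi_nt) else float(row.qsi_nt),
            )


@dataclass
class ClinicalTable:
    """Validated per-patient clinical covariates and endpoints."""

    df: pd.DataFrame
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


def age_to_group(age: float) -> str:
    """10-year age bin; ages above the last bin are folded into 70-79."""
    idx = int((age - 20) // 10)
    idx = min(max(idx, 0), len(AGE_BINS) - 1)
    return AGE_BINS[idx]


def normalize_variant_class(value: str) -> str:
    value = str(value).strip()
    if value in VARIANT_CLASSES:
        return value
    return MAF_CLASS_MAP.get(value, "other")


def _data_header_offset(path: Path, comment: str = "#") -> int:
    """1-based line number of the header row (first non-comment line)."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(comment):
                return i
    return 1


def read_maf(path, column_map: Mapping[str, str] | None = None,
             default_sample_id: str = "sample") -> VariantTable:
    """Read a MAF-style TSV into a :class:`VariantTable`.

    ``column_map`` maps canonical MAF column names to the names actually
    present in the file (absorbs annotation-pipeline dialect differences).
    Rows with unparseable or zero-depth read counts are rejected and
    reported in ``diagnostics`` with their 1-based file line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                      keep_default_na=False)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    for col in MAF_MANDATORY:
        if col not in raw.columns:
            raise FormatError(f"MAF is missing mandatory column '{col}'")
    offset = _data_header_offset(path)  # header line; data starts offset+1

    diagnostics: list[RowDiagnostic] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = offset + 1 + i
        rec = dict(zip(raw.columns, row))
        try:
            alt_count = int(rec["t_alt_count"])
            ref_count = int(rec["t_ref_count"])
        except (TypeError, ValueError):
            diagnostics.append(RowDiagnostic(
                line, "t_alt_count/t_ref_count",
                f"unparseable read counts "
                f"({rec['t_alt_count']!r}/{rec['t_ref_count']!r})"))
            continue
        if alt_count < 0 or ref_count < 0:
            diagnostics.append(RowDiagnostic(
                line, "t_alt_count/t_ref_count", "negative read count"))
            continue
        depth = alt_count + ref_count
        if depth < 1:
            diagnostics.append(RowDiagnostic(
                line, "t_alt_count/t_ref_count", "zero total depth"))
            continue
        try:
            pos = int(rec["Start_Position"])
        except (TypeError, ValueError):
            diagnostics.append(RowDiagnostic(
                line, "Start_Position", f"unparseable position "
                f"{rec['Start_Position']!r}"))
            continue
        rows.append({
            "sample_id": rec.get("Tumor_Sample_Barcode") or default_sample_id,
            "gene": rec["Hugo_Symbol"],
            "chrom": str(rec["Chromosome"]),
            "pos": pos,
            "ref": rec["Reference_Allele"],
            "alt": rec["Tumor_Seq_Allele2"],
            "variant_class": normalize_variant_class(rec["Variant_Classification"]),
            "protein_change": _opt_str(rec.get("Protein_Change")),
            "alt_count": alt_count,
            "ref_count": ref_count,
            "vaf": alt_count / depth,
            "tlod": _opt_float(rec.get("TLOD")),
            "qsi_nt": _opt_float(rec.get("QSI_NT")),
        })
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return VariantTable(df=df, dialect="maf", diagnostics=diagnostics)


def _opt_str(value) -> str | float:
    if value is None or str(value).strip() in ("", "."):
        return np.nan
    return str(value)


def _opt_float(value) -> float:
    if value is None or str(value).strip() in ("", "."):
        return np.nan
    return float(value)


def write_maf(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` back out as MAF-style TSV.

    Round-trips all mandatory columns and row order.
    """
    df = table.df
    out = pd.DataFrame({
        "Hugo_Symbol": df["gene"],
        "Chromosome": df["chrom"],
        "Start_Position": df["pos"],
        "Reference_Allele": df["ref"],
        "Tumor_Seq_Allele2": df["alt"],
        "Variant_Classification": df["variant_class"],
        "t_ref_count": df["ref_count"],
        "t_alt_count": df["alt_count"],
        "Tumor_Sample_Barcode": df["sample_id"],
        "Protein_Change": df["protein_change"],
        "TLOD": df["tlod"],
        "QSI_NT": df["qsi_nt"],
    })
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_vcf_minimal(path, gene_key: str = "GENE", class_key: str = "CLASS",
                     protein_key: str = "PCHANGE") -> VariantTable:
    """Read a minimal VCF 4.x with per-sample AD into a :class:`VariantTable`.

    One row per ALT allele; multi-allelic records are split, each ALT's VAF
    computed against the record's total allelic depth. Symbolic ALTs are
    skipped (counted as a warning diagnostic). A record without AD is a
    format error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise FormatError("VCF has no sample columns (AD is required)")
    sample_id = samples[0]
    rows = []
    diagnostics: list[RowDiagnostic] = []
    n_symbolic = 0
    for v in vcf:
        alts = v.ALT
        symbolic = [a for a in alts if a.startswith("<") or "[" in a or "]" in a]
        if symbolic:
            n_symbolic += len(symbolic)
            alts = [a for a in alts if a not in symbolic]
            if not alts:
                continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(
                f"record {v.CHROM}:{v.POS} lacks AD in FORMAT")
        ad = np.asarray(ad[0], dtype=float)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        depth = float(ad.sum())
        genes = _split_info(v.INFO.get(gene_key), len(v.ALT))
        classes = _split_info(v.INFO.get(class_key), len(v.ALT))
        proteins = _split_info(v.INFO.get(protein_key), len(v.ALT))
        for ai, alt in enumerate(v.ALT):
            if alt in symbolic:
                continue
            alt_count = int(ad[ai + 1]) if ai + 1 < len(ad) else 0
            if depth < 1:
                diagnostics.append(RowDiagnostic(
                    0, "AD", f"zero total depth at {v.CHROM}:{v.POS}"))
                continue
            rows.append({
                "sample_id": sample_id,
                "gene": genes[ai] or "",
                "chrom": v.CHROM,
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": alt,
                "variant_class": normalize_variant_class(classes[ai] or "other"),
                "protein_change": _opt_str(proteins[ai]),
                "alt_count": alt_count,
                "ref_count": int(depth) - alt_count,
                "vaf": alt_count / depth,
                "tlod": _opt_float(v.INFO.get("TLOD")),
                "qsi_nt": _opt_float(v.INFO.get("QSI_NT")),
            })
    if n_symbolic:
        warnings.warn(f"skipped {n_symbolic} symbolic ALT allele(s)")
        diagnostics.append(RowDiagnostic(
            0, "ALT", f"skipped {n_symbolic} symbolic ALT allele(s)"))
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return VariantTable(df=df, dialect="vcf-minimal", diagnostics=diagnostics)


def _split_info(value, n_alt: int) -> list:
    if value is None:
        return [None] * n_alt
    parts = str(value).split(",")
    if len(parts) == n_alt:
        return parts
    return [parts[0]] * n_alt


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_bool(value, allow_missing: bool = False):
    s = str(value).strip().lower()
    if s in ("", ".", "nan", "na", "none"):
        if allow_missing:
            return np.nan
        raise ValueError("missing boolean")
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_clinical(path) -> ClinicalTable:
    """Read and validate the clinical cohort CSV.

    Invariants enforced per row (violations reject the row and are listed in
    ``diagnostics``): event indicators in {0,1}; times >= 0; a TMN event
    implies tmn_time <= os_time; ISS in {1,2,3}; age >= 18. ``smoking`` may
    be missing (kept as NA, never imputed).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty and len(raw.columns) <= 1:
        warnings.warn(f"clinical file {path} is empty")
        return ClinicalTable(df=pd.DataFrame(columns=CLINICAL_REQUIRED + ["age_group", "smoking"]))
    missing = [c for c in CLINICAL_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(f"clinical CSV is missing column(s): {', '.join(missing)}")

    diagnostics: list[RowDiagnostic] = []
    rows = []
    for i, rec in enumerate(raw.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            parsed = _parse_clinical_row(rec)
        except ValueError as exc:
            diagnostics.append(RowDiagnostic(line, exc.args[1] if len(exc.args) > 1 else "?",
                                             str(exc.args[0])))
            continue
        rows.append(parsed)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=CLINICAL_REQUIRED + ["age_group", "smoking"])
    return ClinicalTable(df=df, diagnostics=diagnostics)


def _parse_clinical_row(rec: dict) -> dict:
    def fail(field, msg):
        raise ValueError(msg, field)

    try:
        age = float(rec["age"])
    except ValueError:
        fail("age", f"unparseable age {rec['age']!r}")
    if age < 18:
        fail("age", f"age {age} < 18")
    try:
        iss = int(rec["iss"])
    except ValueError:
        fail("iss", f"unparseable ISS {rec['iss']!r}")
    if iss not in (1, 2, 3):
        fail("iss", f"ISS {iss} not in {{1,2,3}}")
    pl = str(rec["prior_lines"]).strip()
    if pl not in ("0", "1", "2", "3+"):
        if pl.isdigit() and int(pl) >= 3:
            pl = "3+"
        else:
            fail("prior_lines", f"prior_lines {pl!r} not in {{0,1,2,3+}}")
    sex = str(rec["sex"]).strip().upper()[:1]
    if sex not in ("F", "M"):
        fail("sex", f"sex {rec['sex']!r} not F/M")
    out = {
        "patient_id": rec["patient_id"], "age": age,
        "age_group": age_to_group(age), "sex": sex, "iss": iss,
        "prior_lines": pl,
    }
    try:
        out["maintenance"] = _parse_bool(rec["maintenance"])
    except ValueError:
        fail("maintenance", f"maintenance {rec['maintenance']!r} not boolean")
    try:
        out["smoking"] = _parse_bool(rec.get("smoking", ""), allow_missing=True)
    except ValueError:
        fail("smoking", f"smoking {rec.get('smoking')!r} not boolean/missing")
    if "chip" in rec:
        try:
            out["chip"] = _parse_bool(rec["chip"])
        except ValueError:
            fail("chip", f"chip {rec['chip']!r} not boolean")
    for stem in ("os", "pfs", "tmn"):
        try:
            t = float(rec[f"{stem}_time"])
        except ValueError:
            fail(f"{stem}_time", f"unparseable time {rec[f'{stem}_time']!r}")
        try:
            e = int(rec[f"{stem}_event"])
        except ValueError:
            fail(f"{stem}_event", f"unparseable event {rec[f'{stem}_event']!r}")
        if t < 0:
            fail(f"{stem}_time", f"negative time {t}")
        if e not in (0, 1):
            fail(f"{stem}_event", f"event indicator {e} not in {{0,1}}")
        out[f"{stem}_time"], out[f"{stem}_event"] = t, e
    if out["tmn_event"] == 1 and out["tmn_time"] > out["os_time"] + 1e-9:
        fail("tmn_time", f"TMN event at {out['tmn_time']} after os_time "
                         f"{out['os_time']}")
    return out


def write_clinical(table: ClinicalTable | pd.DataFrame, path) -> None:
    df = table.df if isinstance(table, ClinicalTable) else table
    df.to_csv(path, index=False, na_rep="")


def read_pileup(path) -> pd.DataFrame:
    """Read a pileup allele-count TSV (sample_id, chrom, pos, ref, alt,
    alt_count, depth); enforces 0 <= alt_count <= depth."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "chrom", "pos", "ref", "alt", "alt_count", "depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"pileup TSV missing column(s): {', '.join(missing)}")
    bad = (df["alt_count"] < 0) | (df["alt_count"] > df["depth"])
    if bad.any():
        raise FormatError(
            f"pileup rows with alt_count outside [0, depth]: "
            f"{list(df.index[bad][:5])}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_pileup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_contexts(path) -> list[SampleContext]:
    """Read a per-sample QC context TSV into SampleContext records."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["."])
    required = ["sample_id", "contamination", "mean_depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"context TSV missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tf = getattr(row, "tumor_fraction", None)
        tf = None if tf is None or pd.isna(tf) else float(tf)
        out.append(SampleContext(
            sample_id=str(row.sample_id),
            contamination=float(row.contamination),
            tumor_fraction=tf,
            mean_depth=float(row.mean_depth),
        ))
    return out


def write_contexts(contexts: Sequence[SampleContext], path) -> None:
    pd.DataFrame([{
        "sample_id": c.sample_id,
        "contamination": c.contamination,
        "tumor_fraction": np.nan if c.tumor_fraction is None else c.tumor_fraction,
        "mean_depth": c.mean_depth,
    } for c in contexts]).to_csv(path, sep="\t", index=False, na_rep=".")
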