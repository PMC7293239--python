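"""End-to-end orchestration: read inputs, call CHIP, merge with the
clinical table, run the outcome analyses, and write a report bundle with a
reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as cio
from .classifier import (ChipCallSet, DriverRules, FilterThresholds,
                         call_chip, default_driver_rules, summarize_cohort)
from .errors import ConfigurationError, StageError
from .survival import (cif_aalen_johansen, cox_stratified, fisher_exact_2x2,
                       gray_test, km_fit, km_long_frame, logrank,
                       median_survival_table, trend_test, wilcoxon_rank_sum)
from .tracking import MutationId, clonal_relation_summary, track_mutations, \
    tracked_report

log = logging.getLogger("chipcall")

DEFAULT_FORMULAS = {
    "os": "os ~ chip + maintenance strata(age_group, iss, prior_lines)",
    "pfs": "pfs ~ chip + maintenance + chip:maintenance "
           "strata(age_group, iss, prior_lines)",
}

_OUTCOME_COLS = {"os": ("os_time", "os_event"),
                 "pfs": ("pfs_time", "pfs_event"),
                 "tmn": ("tmn_time", "tmn_event")}


@dataclass
class RunConfig:
    variants_path: str
    contexts_path: str
    clinical_path: str
    outdir: str
    rules_path: Optional[str] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    formulas: dict = field(default_factory=lambda: dict(DEFAULT_FORMULAS))
    drop_tumor_contaminated: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in (self.variants_path, self.contexts_path, self.clinical_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input file does not exist: {p}")
        if self.rules_path and not Path(self.rules_path).exists():
            raise ConfigurationError(
                f"rules file does not exist: {self.rules_path}")


_FORMULA_RE = re.compile(
    r"^\s*(\w+)\s*~\s*(.*?)\s*(?:strata\(([^)]*)\))?\s*$")


def parse_formula(formula: str):
    """Parse "outcome ~ a + b + a:b strata(s1, s2)" into
    (outcome, [terms], [strata columns])."""
    m = _FORMULA_RE.match(formula)
    if not m:
        raise ConfigurationError(f"cannot parse model formula: {formula!r}")
    outcome, terms_s, strata_s = m.groups()
    terms = [t.strip() for t in terms_s.split("+") if t.strip()]
    strata = [s.strip() for s in strata_s.split(",")] if strata_s else []
    if outcome not in _OUTCOME_COLS:
        raise ConfigurationError(
            f"unknown outcome {outcome!r} (use os, pfs or tmn)")
    return outcome, terms, strata


def build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design matrix for the given terms; ':' makes a product
    interaction. Booleans are coded 0/1; constant columns are rejected."""
    cols = {}
    for term in terms:
        parts = term.split(":")
        vals = np.ones(len(df))
        for p in parts:
            if p not in df.columns:
                raise ConfigurationError(
                    f"model term {p!r} is not a known column")
            v = df[p]
            if v.dtype == bool or set(v.dropna().unique()) <= {True, False}:
                v = v.astype(float)
            v = pd.to_numeric(v, errors="raise")
            vals = vals * v.to_numpy(dtype=float)
        if np.nanstd(vals) == 0:
            raise ConfigurationError(
                f"model term {term!r} is constant in these data")
        cols[term] = vals
    return pd.DataFrame(cols, index=df.index)


def strata_labels(df: pd.DataFrame, strata_cols: list[str]) -> np.ndarray:
    if not strata_cols:
        return np.zeros(len(df), dtype=int)
    for s in strata_cols:
        if s not in df.columns:
            raise ConfigurationError(f"stratum column {s!r} unknown")
    return df[strata_cols].astype(str).agg("|".join, axis=1).to_numpy()


def fit_formula(df: pd.DataFrame, formula: str):
    """Fit a stratified Cox model from a formula string."""
    outcome, terms, strata_cols = parse_formula(formula)
    tcol, ecol = _OUTCOME_COLS[outcome]
    X = build_design(df, terms)
    return cox_stratified(X, df[tcol].to_numpy(dtype=float),
                          df[ecol].to_numpy(dtype=int),
                          strata=strata_labels(df, strata_cols))


def characteristics_tests(df: pd.DataFrame) -> pd.DataFrame:
    """Table-1 style association battery of covariates against CHIP status
    (Fisher for 2-level categoricals, Wilcoxon for continuous,
    ordered-trend for ordinal; missing values excluded pairwise)."""
    rows = []
    chip = df["chip"].astype(bool)

    def add(name, res):
        rows.append({"characteristic": name, "test": res.name,
                     "statistic": res.statistic, "p": res.pvalue})

    if 0 < chip.sum() < len(chip):
        add("age", wilcoxon_rank_sum(df.loc[~chip, "age"],
                                     df.loc[chip, "age"]))
    else:
        log.warning("age comparison skipped: CHIP status is constant")
    for col in ("sex", "smoking"):
        if col not in df.columns:
            continue
        sub = df[[col, "chip"]].dropna()
        levels = sorted(sub[col].unique())
        if len(levels) == 2:
            tab = [[int(((sub[col] == l) & ~sub["chip"].astype(bool)).sum()),
                    int(((sub[col] == l) & sub["chip"].astype(bool)).sum())]
                   for l in levels]
            add(col, fisher_exact_2x2(tab))
    for col, order in (("iss", [1, 2, 3]),
                       ("prior_lines", ["0", "1", "2", "3+"])):
        sub = df[[col, "chip"]].dropna()
        cats = pd.Categorical(sub[col], categories=order, ordered=True)
        try:
            add(col, trend_test(sub["chip"].astype(float).to_numpy(), cats))
        except Exception as exc:  # < 3 populated levels
            log.warning("trend test for %s skipped: %s", col, exc)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute read -> call -> merge -> outcomes -> report.

    Returns a dict of in-memory results; writes the report bundle under
    ``cfg.outdir``. Any stage failure removes partial outputs and raises a
    :class:`~chipcall.errors.StageError` naming the stage.
    """
    logging.basicConfig(level=cfg.log_level)
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        return _run_stages(cfg, outdir, emit)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_stages(cfg: RunConfig, outdir: Path, emit) -> dict:
    stage = "read"
    try:
        variants = cio.read_maf(cfg.variants_path)
        contexts = cio.read_contexts(cfg.contexts_path)
        clinical = cio.read_clinical(cfg.clinical_path)
        rules = DriverRules.from_yaml(cfg.rules_path) if cfg.rules_path \
            else default_driver_rules()
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "call_chip"
    try:
        callset = call_chip(
            variants, contexts, rules, cfg.thresholds,
            tumor_fraction_policy="drop" if cfg.drop_tumor_contaminated
            else "flag")
        summary = summarize_cohort(callset)
        emit("chip_calls.tsv",
             lambda p: callset.to_frame().to_csv(p, sep="\t", index=False))
        emit("per_sample.tsv",
             lambda p: callset.per_sample.to_csv(p, sep="\t", index=False))
        summ_json = {
            "n_patients": summary.n_patients,
            "n_chip_patients": summary.n_chip_patients,
            "prevalence": summary.prevalence,
            "median_vaf": summary.median_vaf,
            "multi_gene_fraction": summary.multi_gene_fraction(),
            "gene_patient_counts": summary.gene_patient_counts.to_dict(),
        }
        emit("cohort_summary.json",
             lambda p: Path(p).write_text(json.dumps(summ_json, indent=1)))
        log.info("CHIP prevalence %.1f%% (%d/%d)", 100 * summary.prevalence,
                 summary.n_chip_patients, summary.n_patients)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "merge"
    try:
        clin = clinical.df.copy()
        if "chip" in clin.columns:
            clin = clin.rename(columns={"chip": "chip_true"})
        merged = clin.merge(
            callset.per_sample[["sample_id", "chip", "n_genes"]],
            left_on="patient_id", right_on="sample_id", how="inner")
        if merged.empty:
            raise ConfigurationError(
                "no overlap between clinical patient_ids and sample contexts")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "outcomes"
    try:
        results: dict = {"summary": summ_json, "models": {}}
        emit("characteristics_tests.tsv",
             lambda p: characteristics_tests(merged).to_csv(
                 p, sep="\t", index=False))
        for name, formula in cfg.formulas.items():
            fit = fit_formula(merged, formula)
            results["models"][name] = fit
            emit(f"cox_{name}.tsv",
                 lambda p, f=fit: f.summary().to_csv(p, sep="\t", index=False))
        # KM by CHIP and by CHIP x maintenance, with log-rank batteries
        for oc in ("os", "pfs"):
            tcol, ecol = _OUTCOME_COLS[oc]
            curves = km_fit(merged[tcol], merged[ecol],
                            merged["chip"].map({True: "CHIP", False: "no CHIP"}))
            emit(f"km_{oc}_by_chip.tsv",
                 lambda p, c=curves: km_long_frame(c).to_csv(
                     p, sep="\t", index=False))
            emit(f"median_{oc}_by_chip.tsv",
                 lambda p, c=curves: median_survival_table(c).to_csv(
                     p, sep="\t", index=False))
            g4 = (merged["chip"].map({True: "CHIP", False: "no CHIP"})
                  + " / " + merged["maintenance"].map(
                      {True: "IMiD", False: "no IMiD"}))
            overall, pairs = logrank(merged[tcol], merged[ecol], g4,
                                     pairwise=True)
            lr = {"overall": {"stat": overall.statistic, "df": overall.df,
                              "p": overall.pvalue},
                  "pairwise": {f"{a} vs {b}": r.pvalue
                               for (a, b), r in pairs.items()}}
            emit(f"logrank_{oc}_chip_maintenance.json",
                 lambda p, d=lr: Path(p).write_text(json.dumps(d, indent=1)))
            results[f"logrank_{oc}"] = lr
        # competing risks: TMN (cause 1) vs death (cause 2)
        tmn_type = np.where(merged["tmn_event"] == 1, 1,
                            np.where(merged["os_event"] == 1, 2, 0))
        for split in ("maintenance", "chip"):
            grp = merged[split].map({True: split, False: f"no {split}"})
            if grp.nunique() < 2:
                log.warning("competing-risk split by %s skipped: "
                            "only one level present", split)
                continue
            cifs = cif_aalen_johansen(merged["tmn_time"], tmn_type, grp)
            frames = []
            for g, c in cifs.items():
                f = c.to_frame()
                f.insert(0, "group", g)
                frames.append(f)
            emit(f"cif_tmn_by_{split}.tsv",
                 lambda p, fr=frames: pd.concat(fr, ignore_index=True).to_csv(
                     p, sep="\t", index=False))
            gr = gray_test(merged["tmn_time"], tmn_type, grp, cause=1)
            results[f"gray_tmn_by_{split}"] = gr
            emit(f"gray_tmn_by_{split}.json",
                 lambda p, g_=gr: Path(p).write_text(json.dumps(
                     {"stat": g_.statistic, "df": g_.df, "p": g_.pvalue},
                     indent=1)))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "manifest"
    try:
        cfg_dict = dataclasses.asdict(cfg)
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "versions": _versions(),
        }
        emit("manifest.json",
             lambda p: Path(p).write_text(json.dumps(manifest, indent=1,
                                                     default=str)))
        results["manifest"] = manifest
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    return results


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"chipcall": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


# ---------------------------------------------------------------------------
# tracking from tables (CLI-facing)
# ---------------------------------------------------------------------------

def track_from_tables(mutations: pd.DataFrame,
                      pileups: list[pd.DataFrame],
                      contexts: list,
                      alpha: float = 0.01,
                      base_error: float = 1e-3):
    """Track each patient's mutation list across timepoint pileups.

    ``mutations`` needs columns patient_id, chrom, pos, ref, alt[, gene] and
    one sample column per timepoint (sample_t1, sample_t2, ...).
    ``contexts`` is a flat list of SampleContext covering all samples.
    """
    ctx_by_id = {c.sample_id: c for c in contexts}
    sample_cols = [c for c in mutations.columns if c.startswith("sample_t")]
    if len(sample_cols) != len(pileups):
        raise ConfigurationError(
            f"{len(sample_cols)} sample_t* columns but {len(pileups)} pileups")
    out = {}
    for pid, sub in mutations.groupby("patient_id"):
        ids = [MutationId(chrom=str(r.chrom), pos=int(r.pos), ref=r.ref,
                          alt=r.alt, gene=getattr(r, "gene", ""))
               for r in sub.itertuples(index=False)]
        ctxs = []
        for col in sample_cols:
            sid = str(sub[col].iloc[0])
            if sid not in ctx_by_id:
                raise ConfigurationError(f"no context for sample {sid!r}")
            ctxs.append(ctx_by_id[sid])
        out[str(pid)] = track_mutations(ids, pileups, ctxs, alpha=alpha,
                                        base_error=base_error)
    return out


__all__ = [
    "RunConfig", "run_pipeline", "parse_formula", "build_design",
    "fit_formula", "characteristics_tests", "track_from_tables",
    "clonal_relation_summary", "tracked_report", "DEFAULT_FORMULAS",
]
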