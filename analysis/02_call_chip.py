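#!/usr/bin/env python
"""Run the CHIP caller on the simulated cohort and summarise the mutational
spectrum (prevalence, gene ranking, VAF distribution, comutation counts).

Reads results/cohort/ (generating it first if absent); writes per-variant
verdicts and the cohort summary under results/chip/.
"""

import json
import subprocess
import sys
from pathlib import Path

from chipcall import io as cio
from chipcall.classifier import call_chip, default_driver_rules, \
    summarize_cohort

COHORT = Path("results/cohort")
OUTDIR = Path("results/chip")


def main() -> None:
    if not (COHORT / "variants.maf.tsv").exists():
        subprocess.run([sys.executable, "analysis/01_simulate_cohort.py"],
                       check=True)
    variants = cio.read_maf(COHORT / "variants.maf.tsv")
    contexts = cio.read_contexts(COHORT / "contexts.tsv")
    callset = call_chip(variants, contexts, default_driver_rules())
    summary = summarize_cohort(callset)

    OUTDIR.mkdir(parents=True, exist_ok=True)
    callset.to_frame().to_csv(OUTDIR / "chip_calls.tsv", sep="\t",
                              index=False)
    callset.per_sample.to_csv(OUTDIR / "per_sample.tsv", sep="\t",
                              index=False)
    with open(OUTDIR / "cohort_summary.json", "w") as fh:
        json.dump({
            "n_patients": summary.n_patients,
            "n_chip_patients": summary.n_chip_patients,
            "prevalence": summary.prevalence,
            "median_vaf": summary.median_vaf,
            "multi_gene_fraction": summary.multi_gene_fraction(),
            "vaf_ge_0.10_fraction": summary.vaf_ge_fraction(0.10),
            "gene_patient_counts": summary.gene_patient_counts.to_dict(),
        }, fh, indent=1)

    print(f"CHIP-positive: {summary.n_chip_patients}/{summary.n_patients} "
          f"({100 * summary.prevalence:.1f}%)")
    print(f"median retained-driver VAF: {summary.median_vaf:.4f}")
    print(f"carriers with >= 2 mutated genes: "
          f"{100 * summary.multi_gene_fraction():.1f}%")
    print(f"carriers with a clone at VAF >= 0.10: "
          f"{100 * summary.vaf_ge_fraction(0.10):.1f}%")
    print("patients mutated per gene:")
    for gene, n in summary.gene_patient_counts.items():
        print(f"  {gene:8s} {n}")


if __name__ == "__main__":
    main()
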