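"""Force-calling of a fixed mutation list against pileup allele counts,
and clonal-relation assessment between sequential samples.

Force-calling asks, for a list of genomic coordinates called in one sample,
how many reads support the alternate allele in another sample from the same
patient. A mutation is *detected* when its alternate-read count exceeds, at
significance ``alpha``, what sequencing error plus cross-sample
contamination could explain (one-sided exact binomial test against rate
``base_error + c/3``). Because detection is depth- and error-driven rather
than a fixed allele-fraction cutoff, clones well below the discovery VAF
threshold of 0.01 can be recovered in deep pileups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import SampleContext
from .errors import ConfigurationError

DEFAULT_BASE_ERROR = 1e-3


@dataclass(frozen=True)
class MutationId:
    """Identity of a tracked mutation."""
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""

    @property
    def key(self):
        return (str(self.chrom), int(self.pos), self.ref, self.alt)


@dataclass
class TimepointCall:
    """Force-call result for one mutation at one timepoint."""
    sample_id: str
    alt_count: Optional[int]     # None when uncovered
    depth: Optional[int]
    vaf: Optional[float]
    detected: Optional[bool]     # None when uncovered
    covered: bool
    p_value: Optional[float] = None


@dataclass
class TrackedMutation:
    """One mutation followed across ordered timepoints."""
    mutation: MutationId
    timepoints: list[TimepointCall] = field(default_factory=list)

    @property
    def fold_change(self) -> Optional[float]:
        """Ratio of last-timepoint VAF to first-timepoint VAF; undefined
        (None) when the earlier VAF is 0 or either timepoint is uncovered."""
        if len(self.timepoints) < 2:
            return None
        first, last = self.timepoints[0], self.timepoints[-1]
        if not (first.covered and last.covered):
            return None
        if not first.vaf:
            return None
        return last.vaf / first.vaf

    def detected_at(self, i: int) -> bool:
        return bool(self.timepoints[i].covered and self.timepoints[i].detected)


def detection_test(alt_count: int, depth: int, contamination: float,
                   base_error: float = DEFAULT_BASE_ERROR,
                   rate_factor: float = 3.0) -> tuple[bool, float]:
    """One-sided exact binomial test of alt support against the
    error+contamination rate; returns (detected at alpha=caller's choice is
    applied upstream, p-value)."""
    p0 = base_error + contamination / rate_factor
    pval = float(stats.binom.sf(alt_count - 1, depth, p0)) if alt_count > 0 else 1.0
    return pval


def force_call(mutations: Sequence[MutationId], pileups: pd.DataFrame,
               ctx: SampleContext, alpha: float = 0.01,
               base_error: float = DEFAULT_BASE_ERROR,
               rate_factor: float = 3.0) -> list[TimepointCall]:
    """Force-call a mutation list against one sample's pileup counts.

    ``pileups`` is the validated frame from :func:`chipcall.io.read_pileup`
    restricted to (or at least containing) ``ctx.sample_id``. Mutations
    without a pileup row, or with zero depth, are reported as uncovered.
    The measured VAF is reported whether or not the detection test rejects.
    """
    rows = pileups[pileups["sample_id"].astype(str) == ctx.sample_id]
    by_site = {(str(r.chrom), int(r.pos), r.ref, r.alt): (int(r.alt_count), int(r.depth))
               for r in rows.itertuples(index=False)}
    out: list[TimepointCall] = []
    for m in mutations:
        hit = by_site.get(m.key)
        if hit is None or hit[1] == 0:
            out.append(TimepointCall(sample_id=ctx.sample_id, alt_count=None,
                                     depth=None, vaf=None, detected=None,
                                     covered=False))
            continue
        alt, depth = hit
        pval = detection_test(alt, depth, ctx.contamination, base_error,
                              rate_factor)
        out.append(TimepointCall(
            sample_id=ctx.sample_id, alt_count=alt, depth=depth,
            vaf=alt / depth, detected=bool(pval < alpha), covered=True,
            p_value=pval))
    return out


def track_mutations(mutations: Sequence[MutationId],
                    pileups_by_timepoint: Sequence[pd.DataFrame],
                    contexts: Sequence[SampleContext],
                    alpha: float = 0.01,
                    base_error: float = DEFAULT_BASE_ERROR,
                    rate_factor: float = 3.0) -> list[TrackedMutation]:
    """Force-call a mutation list across ordered timepoints (e.g. stem-cell
    product at transplant, then TMN diagnosis)."""
    if len(pileups_by_timepoint) != len(contexts):
        raise ConfigurationError(
            "need one SampleContext per timepoint pileup table")
    tracked = [TrackedMutation(mutation=m) for m in mutations]
    for pileup, ctx in zip(pileups_by_timepoint, contexts):
        calls = force_call(mutations, pileup, ctx, alpha, base_error,
                           rate_factor)
        for t, c in zip(tracked, calls):
            t.timepoints.append(c)
    return tracked


@dataclass
class ClonalRelationSummary:
    """Cohort counts of shared vs. timepoint-private detected mutations."""
    n_patients: int                  # with a determinate verdict
    n_clonally_related: int          # >= 1 mutation detected at both timepoints
    n_later_only: int                # detected only at the later timepoint
    n_earlier_only: int
    n_indeterminate: int             # all sites uncovered at a timepoint
    per_patient: dict[str, Optional[bool]] = field(default_factory=dict)


def clonal_relation_summary(
        tracked_by_patient: Mapping[str, Sequence[TrackedMutation]]
) -> ClonalRelationSummary:
    """Classify each patient as clonally related (some mutation detected at
    both first and last timepoint) or not; patients whose sites are all
    uncovered at either timepoint are indeterminate and excluded from the
    denominator."""
    per_patient: dict[str, Optional[bool]] = {}
    n_related = n_later = n_earlier = n_indet = 0
    for patient, muts in tracked_by_patient.items():
        muts = list(muts)
        if not muts:
            per_patient[patient] = None
            n_indet += 1
            continue
        covered_first = any(m.timepoints[0].covered for m in muts)
        covered_last = any(m.timepoints[-1].covered for m in muts)
        if not (covered_first and covered_last):
            per_patient[patient] = None
            n_indet += 1
            continue
        shared = any(m.detected_at(0) and m.detected_at(-1) for m in muts)
        later_only = any(m.detected_at(-1) and not m.detected_at(0)
                         for m in muts)
        earlier_only = any(m.detected_at(0) and not m.detected_at(-1)
                           for m in muts)
        per_patient[patient] = shared
        if shared:
            n_related += 1
        elif later_only:
            n_later += 1
        elif earlier_only:
            n_earlier += 1
    n_det = sum(v is not None for v in per_patient.values())
    return ClonalRelationSummary(
        n_patients=n_det, n_clonally_related=n_related,
        n_later_only=n_later, n_earlier_only=n_earlier,
        n_indeterminate=n_indet, per_patient=per_patient)


def tracked_report(tracked_by_patient: Mapping[str, Sequence[TrackedMutation]]
                   ) -> pd.DataFrame:
    """Long-format report: one row per (patient, mutation, timepoint)."""
    rows = []
    for patient, muts in tracked_by_patient.items():
        for m in muts:
            for i, tp in enumerate(m.timepoints):
                rows.append({
                    "patient_id": patient, "gene": m.mutation.gene,
                    "chrom": m.mutation.chrom, "pos": m.mutation.pos,
                    "ref": m.mutation.ref, "alt": m.mutation.alt,
                    "timepoint": i, "sample_id": tp.sample_id,
                    "alt_count": tp.alt_count, "depth": tp.depth,
                    "vaf": tp.vaf, "covered": tp.covered,
                    "detected": tp.detected,
                    "fold_change": m.fold_change if i == len(m.timepoints) - 1
                    else np.nan,
                })
    return pd.DataFrame(rows)
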