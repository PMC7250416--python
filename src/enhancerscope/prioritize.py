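"""Multi-evidence candidate-enhancer prioritization.

Evidence per candidate DHS: reporter-assay activity class and rank,
the number of transcription-factor peak sets binding it, whether it
lies between a convergent CTCF pair, and its promoter-contact value
(virtual-4C signal at the DHS bin, plus overlap with called 4C
interactions). Candidates are ordered lexicographically — activity
class, then TF-overlap count, then contact value, then activity FC,
with genomic position as the deterministic tie-break — which keeps the
integration auditable instead of hiding it behind invented weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from enhancerscope.capstarr import DhsActivityRecord, _CLASS_ORDER
from enhancerscope.intervals import (
    GenomicInterval,
    SignalTrack,
    overlapping_sets,
)

__all__ = ["CandidateReport", "ctcf_flanking", "prioritize", "report_table"]


@dataclass
class CandidateReport:
    dhs: GenomicInterval
    activity_class: str
    activity_rank: int | None
    activity_fc: float | None
    top_fraction_flag: bool
    tf_overlap_count: int
    tf_overlap_names: list[str]
    ctcf_flanked: bool
    promoter_contact: float
    contact_call_overlap: bool
    priority_rank: int = 0


def ctcf_flanking(
    dhs: GenomicInterval, ctcf_sites: Sequence[GenomicInterval]
) -> bool:
    """True iff the nearest CTCF site upstream of the DHS is forward
    oriented and the nearest downstream site reverse oriented (a
    convergent pair bracketing the candidate). Missing a side -> False.
    """
    upstream = [s for s in ctcf_sites if s.chrom == dhs.chrom and s.end <= dhs.start]
    downstream = [s for s in ctcf_sites if s.chrom == dhs.chrom and s.start >= dhs.end]
    if not upstream or not downstream:
        return False
    nearest_up = max(upstream, key=lambda s: s.end)
    nearest_down = min(downstream, key=lambda s: s.start)
    return nearest_up.strand == "+" and nearest_down.strand == "-"


def _contact_value(track: SignalTrack, dhs: GenomicInterval) -> float:
    """Track value at the DHS midpoint bin (NaN-safe, 0 if uncovered)."""
    mid = dhs.midpoint
    idx = np.searchsorted(track.starts, mid, side="right") - 1
    if idx < 0 or mid >= track.ends[idx]:
        return 0.0
    v = float(track.values[idx])
    return 0.0 if np.isnan(v) else v


def prioritize(
    records: Sequence[DhsActivityRecord],
    tf_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    ctcf_sites: Sequence[GenomicInterval],
    contact_track: SignalTrack | None = None,
    interaction_calls: Sequence[GenomicInterval] | None = None,
) -> list[CandidateReport]:
    """Rank candidates by activity class, TF overlap, promoter contact
    and activity FC (in that order), ties broken by position.

    Deterministic and invariant to input row order; improving any one
    evidence dimension can only improve (or keep) a candidate's rank.
    """
    reports = []
    for r in records:
        names = overlapping_sets(r.dhs, tf_peak_sets)
        contact = (
            _contact_value(contact_track, r.dhs) if contact_track is not None else 0.0
        )
        call_overlap = bool(
            interaction_calls
            and any(r.dhs.overlaps(c) for c in interaction_calls)
        )
        reports.append(
            CandidateReport(
                dhs=r.dhs,
                activity_class=r.activity_class or "undefined",
                activity_rank=r.rank,
                activity_fc=r.fc,
                top_fraction_flag=r.top_fraction_flag,
                tf_overlap_count=len(names),
                tf_overlap_names=names,
                ctcf_flanked=ctcf_flanking(r.dhs, ctcf_sites),
                promoter_contact=contact,
                contact_call_overlap=call_overlap,
            )
        )
    reports.sort(
        key=lambda c: (
            -_CLASS_ORDER.get(c.activity_class, -1),
            -c.tf_overlap_count,
            -c.promoter_contact,
            -(c.activity_fc if c.activity_fc is not None else -np.inf),
            c.dhs.chrom,
            c.dhs.start,
        )
    )
    for i, c in enumerate(reports, start=1):
        c.priority_rank = i
    return reports


def report_table(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "priority_rank": [c.priority_rank for c in reports],
            "name": [c.dhs.name for c in reports],
            "chrom": [c.dhs.chrom for c in reports],
            "start": [c.dhs.start for c in reports],
            "end": [c.dhs.end for c in reports],
            "activity_class": [c.activity_class for c in reports],
            "activity_fc": [c.activity_fc for c in reports],
            "activity_rank": [c.activity_rank for c in reports],
            "top_fraction": [c.top_fraction_flag for c in reports],
            "tf_overlap_count": [c.tf_overlap_count for c in reports],
            "tf_overlap_names": [",".join(c.tf_overlap_names) for c in reports],
            "ctcf_flanked": [c.ctcf_flanked for c in reports],
            "promoter_contact": [c.promoter_contact for c in reports],
            "contact_call_overlap": [c.contact_call_overlap for c in reports],
        }
    )
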