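"""Reporter-assay enhancer-activity scoring, classification and ranking.

Activity per candidate DHS is the fold change (FC) of FPKM in the
screen library over the plasmid input library. DHSs with 1.5 <= FC < 3
are weak enhancers and FC >= 3 strong enhancers (the operative
thresholds of the assay); candidates are ranked by descending FC and
the top fraction (default 5%) flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from enhancerscope.intervals import GenomicInterval

__all__ = [
    "ActivityClass",
    "DhsActivityRecord",
    "compute_fpkm",
    "classify_activity",
    "replicate_merge",
    "rank_dhs",
    "count_active",
    "records_from_counts",
    "activity_table",
    "WEAK_THRESHOLD",
    "STRONG_THRESHOLD",
    "TOP_FRACTION",
]

WEAK_THRESHOLD = 1.5
STRONG_THRESHOLD = 3.0
TOP_FRACTION = 0.05

ActivityClass = Literal["inactive", "weak", "strong"]
_CLASS_ORDER = {"inactive": 0, "weak": 1, "strong": 2}


@dataclass
class DhsActivityRecord:
    dhs: GenomicInterval
    fpkm_screen: float
    fpkm_input: float
    fc: float | None
    activity_class: ActivityClass | None = None
    rank: int | None = None
    top_fraction_flag: bool = False


def compute_fpkm(count: float, fragment_length: int, library_size: int) -> float:
    """Fragments per kilobase per million mapped reads."""
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / (fragment_length / 1e3) / (library_size / 1e6)


def classify_activity(
    fc: float,
    weak_threshold: float = WEAK_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
) -> ActivityClass:
    """inactive below the weak threshold, weak in [1.5, 3), strong at >= 3."""
    if not math.isfinite(fc) or fc < 0:
        raise ValueError(f"fold-change must be finite and non-negative, got {fc}")
    if fc < weak_threshold:
        return "inactive"
    if fc < strong_threshold:
        return "weak"
    return "strong"


def replicate_merge(
    fc_values: Sequence[float], method: Literal["mean"] = "mean"
) -> float:
    """Merge replicate fold-changes (arithmetic mean)."""
    vals = [v for v in fc_values]
    if not vals or any(not math.isfinite(v) for v in vals):
        raise ValueError("replicate FCs must be finite and non-empty")
    if method != "mean":
        raise ValueError(f"unknown merge method {method!r}")
    return float(np.mean(vals))


def rank_dhs(
    records: Sequence[DhsActivityRecord],
    top_fraction: float = TOP_FRACTION,
) -> list[DhsActivityRecord]:
    """Rank records by descending FC; flag the top fraction.

    Records with undefined FC (zero input) are excluded from ranking and
    keep ``rank=None``. Ties are broken by genomic position for
    determinism. The flag is set for rank <= ceil(top_fraction * N)
    where N counts rankable records.
    """
    rankable = [r for r in records if r.fc is not None]
    order = sorted(
        range(len(rankable)),
        key=lambda i: (-rankable[i].fc, rankable[i].dhs.chrom, rankable[i].dhs.start),
    )
    n_top = math.ceil(top_fraction * len(rankable)) if rankable else 0
    ranked = {id(rankable[i]): pos + 1 for pos, i in enumerate(order)}
    out = []
    for r in records:
        rk = ranked.get(id(r))
        out.append(replace(r, rank=rk, top_fraction_flag=rk is not None and rk <= n_top))
    return out


def count_active(records: Sequence[DhsActivityRecord]) -> tuple[int, int]:
    """(number of weak-or-strong DHSs, total DHSs)."""
    if not records:
        raise ValueError("no records")
    n_active = sum(
        1 for r in records if r.activity_class in ("weak", "strong")
    )
    return n_active, len(records)


def records_from_counts(
    replicate_tables: Sequence[pd.DataFrame],
    dhs_names: Iterable[str] | None = None,
    weak_threshold: float = WEAK_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
    top_fraction: float = TOP_FRACTION,
    merge: Literal["mean", "pooled"] = "mean",
) -> list[DhsActivityRecord]:
    """Build ranked activity records from per-replicate count tables.

    Each table needs columns fragment_id, chrom, start, end,
    screen_count, input_count. With ``merge="mean"`` (default) FPKMs and
    the FC are computed per replicate against that replicate's library
    sizes and replicate FCs averaged; ``merge="pooled"`` sums counts
    across replicates first and computes one FC. ``dhs_names`` restricts
    the output to the candidate fragments (default: all fragments).
    """
    if not replicate_tables:
        raise ValueError("need at least one replicate table")
    if merge == "pooled" and len(replicate_tables) > 1:
        pooled = replicate_tables[0].copy()
        for df in replicate_tables[1:]:
            pooled["screen_count"] = pooled["screen_count"] + df["screen_count"].to_numpy()
            pooled["input_count"] = pooled["input_count"] + df["input_count"].to_numpy()
        replicate_tables = [pooled]
    elif merge not in ("mean", "pooled"):
        raise ValueError(f"unknown merge method {merge!r}")
    keep = set(dhs_names) if dhs_names is not None else None
    per_rep_fc: list[dict[str, float | None]] = []
    fpkm_s: dict[str, list[float]] = {}
    fpkm_i: dict[str, list[float]] = {}
    meta: dict[str, GenomicInterval] = {}
    for df in replicate_tables:
        lib_screen = int(df["screen_count"].sum())
        lib_input = int(df["input_count"].sum())
        fcs: dict[str, float | None] = {}
        for row in df.itertuples(index=False):
            fid = row.fragment_id
            if keep is not None and fid not in keep:
                continue
            length = row.end - row.start
            fs = compute_fpkm(row.screen_count, length, lib_screen)
            fi = compute_fpkm(row.input_count, length, lib_input)
            fcs[fid] = fs / fi if fi > 0 else None
            fpkm_s.setdefault(fid, []).append(fs)
            fpkm_i.setdefault(fid, []).append(fi)
            meta.setdefault(
                fid, GenomicInterval(row.chrom, row.start, row.end, fid)
            )
        per_rep_fc.append(fcs)
    records = []
    for fid, iv in meta.items():
        reps = [fcs.get(fid) for fcs in per_rep_fc]
        if any(v is None for v in reps):
            fc = None
            cls = None
        else:
            fc = replicate_merge([v for v in reps if v is not None])
            cls = classify_activity(fc, weak_threshold, strong_threshold)
        records.append(
            DhsActivityRecord(
                dhs=iv,
                fpkm_screen=float(np.mean(fpkm_s[fid])),
                fpkm_input=float(np.mean(fpkm_i[fid])),
                fc=fc,
                activity_class=cls,
            )
        )
    return rank_dhs(records, top_fraction)


def activity_table(records: Sequence[DhsActivityRecord]) -> pd.DataFrame:
    """Flat report table for TSV export."""
    return pd.DataFrame(
        {
            "name": [r.dhs.name for r in records],
            "chrom": [r.dhs.chrom for r in records],
            "start": [r.dhs.start for r in records],
            "end": [r.dhs.end for r in records],
            "fpkm_screen": [r.fpkm_screen for r in records],
            "fpkm_input": [r.fpkm_input for r in records],
            "fc": [r.fc if r.fc is not None else np.nan for r in records],
            "activity_class": [r.activity_class or "undefined" for r in records],
            "rank": [r.rank if r.rank is not None else -1 for r in records],
            "top_fraction": [r.top_fraction_flag for r in records],
        }
    )
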