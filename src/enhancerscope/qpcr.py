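"""ddCt relative-expression analysis and differential coverage tracks.

Relative expression between groups is computed by the delta Ct method:
per-replicate dCt = Ct(target) - Ct(housekeeping), relative expression
= 2^-(dCt_test - mean dCt_reference) assuming 100% amplification
efficiency, with an unpaired two-tailed Student's t-test on the dCt
values across replicates. A 2-cycle ddCt therefore corresponds exactly
to a four-fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from enhancerscope.intervals import GenomicInterval, SignalTrack

__all__ = [
    "ExpressionResult",
    "read_ct_table",
    "validate_ct_table",
    "delta_ct",
    "relative_expression",
    "fold_induction",
    "differential_track",
    "lift_track_to_reference",
    "DEFAULT_HOUSEKEEPING",
]

DEFAULT_HOUSEKEEPING = "Rpl32"


@dataclass
class ExpressionResult:
    amplicon: str
    test_group: str
    reference_group: str
    relative_expression: float  # mean over replicates, reference = 1
    sd: float | None
    t_statistic: float | None
    p_value: float | None
    n_replicates: int
    per_replicate: np.ndarray | None = None


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    required = {"group", "amplicon", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = df["ct"].to_numpy(float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("all Ct values must be finite and positive")


def delta_ct(
    table: pd.DataFrame,
    amplicon: str,
    group: str,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
) -> pd.Series:
    """Per-replicate dCt = Ct(amplicon) - Ct(housekeeping), paired by
    replicate id (row order is irrelevant)."""
    sub = table[table["group"] == group]
    tgt = sub[sub["amplicon"] == amplicon].set_index("replicate")["ct"]
    hk = sub[sub["amplicon"] == housekeeping].set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"no Ct rows for amplicon {amplicon!r} in group {group!r}")
    missing = sorted(set(tgt.index) - set(hk.index))
    if missing:
        raise ValueError(
            f"housekeeping {housekeeping!r} missing for replicate(s) {missing} "
            f"in group {group!r}"
        )
    return (tgt - hk.reindex(tgt.index)).sort_index()


def relative_expression(
    table: pd.DataFrame,
    amplicon: str,
    test_group: str,
    reference_group: str,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
    efficiency: float = 2.0,
) -> ExpressionResult:
    """Fold change of the test group over the reference group.

    Per-replicate relative expression is efficiency^-(dCt_test - mean
    dCt_reference); the t-test (unpaired, two-tailed) is computed on the
    dCt values of the two groups.
    """
    dct_test = delta_ct(table, amplicon, test_group, housekeeping)
    dct_ref = delta_ct(table, amplicon, reference_group, housekeeping)
    rel = np.power(efficiency, -(dct_test.to_numpy() - dct_ref.mean()))
    n = len(rel)
    if n < 2 or len(dct_ref) < 2:
        warnings.warn(
            f"single replicate for {amplicon}: sd and p-value unavailable",
            stacklevel=2,
        )
        sd = t = p = None
    else:
        sd = float(np.std(rel, ddof=1))
        if np.var(dct_test) == 0 and np.var(dct_ref) == 0:
            # degenerate noiseless case: identical groups are a null
            # result, distinct groups are separated with certainty
            equal = float(dct_test.mean()) == float(dct_ref.mean())
            t = 0.0 if equal else float(np.sign(dct_test.mean() - dct_ref.mean()) * np.inf)
            p = 1.0 if equal else 0.0
        else:
            t, p = stats.ttest_ind(dct_test, dct_ref, equal_var=True)
            t, p = float(t), float(p)
    return ExpressionResult(
        amplicon=amplicon,
        test_group=test_group,
        reference_group=reference_group,
        relative_expression=float(rel.mean()),
        sd=sd,
        t_statistic=t,
        p_value=p,
        n_replicates=n,
        per_replicate=rel,
    )


def fold_induction(
    table: pd.DataFrame,
    amplicon: str,
    stim_group: str,
    unstim_group: str,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
) -> ExpressionResult:
    """Relative expression of stimulated over unstimulated cells within
    one genotype (loss of induction in the mutant shows as a fold near 1)."""
    return relative_expression(
        table, amplicon, stim_group, unstim_group, housekeeping
    )


# ---------------------------------------------------------------------------
# Differential coverage tracks


def lift_track_to_reference(
    track: SignalTrack, deletion: GenomicInterval
) -> SignalTrack:
    """Map a mutant-coordinate track back to wt coordinates.

    Positions at or beyond the deletion start shift right by the
    deletion width; the deleted interval itself has no mutant
    counterpart and is emitted with NaN.
    """
    w = deletion.width
    starts, ends, values = [], [], []
    for s, e, v in zip(track.starts, track.ends, track.values):
        if e <= deletion.start:
            starts.append(s); ends.append(e); values.append(v)
        elif s >= deletion.start:
            starts.append(s + w); ends.append(e + w); values.append(v)
        else:  # interval straddles the breakpoint: split it
            starts.extend([s, deletion.start + w])
            ends.extend([deletion.start, e + w])
            values.extend([v, v])
    starts.append(deletion.start)
    ends.append(deletion.end)
    values.append(np.nan)
    order = np.argsort(starts, kind="stable")
    return SignalTrack(
        track.chrom,
        np.asarray(starts)[order],
        np.asarray(ends)[order],
        np.asarray(values)[order],
    )


def differential_track(
    wt: SignalTrack,
    mut: SignalTrack,
    deletion: GenomicInterval | None = None,
) -> SignalTrack:
    """Per-base difference wt - mut on merged breakpoints.

    When ``deletion`` is given, the mutant track is first lifted back to
    wt coordinates; the deleted interval is reported as missing (NaN).
    """
    if wt.chrom != mut.chrom:
        raise ValueError(
            f"tracks on different chromosomes: {wt.chrom!r} vs {mut.chrom!r}"
        )
    if deletion is not None:
        mut = lift_track_to_reference(mut, deletion)
    edges = np.unique(
        np.concatenate([wt.starts, wt.ends, mut.starts, mut.ends])
    )
    starts, ends = edges[:-1], edges[1:]

    def value_at(track: SignalTrack, s: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(track.starts, s, side="right") - 1
        vals = np.zeros(len(s))
        ok = idx >= 0
        inside = np.zeros(len(s), dtype=bool)
        inside[ok] = s[ok] < track.ends[idx[ok]]
        vals[inside] = track.values[idx[inside]]
        return vals

    diff = value_at(wt, starts) - value_at(mut, starts)
    return SignalTrack(wt.chrom, starts, ends, diff)
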