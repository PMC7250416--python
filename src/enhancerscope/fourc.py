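"""4C-seq fragment-profile analysis.

Per-fragment viewpoint contact counts are smoothed with a running mean
(window of 21 fragments), quantile-normalized across samples, and
screened for interactions with a simplified viewpoint-profile caller:
the monotone-decaying background on each side of the viewpoint is
estimated by isotonic regression against distance (with a second pass
that excludes the most enriched fragments from the fit), and runs of
fragments whose enrichment over background clears a residual-quantile
threshold are merged into interaction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from enhancerscope.intervals import FragmentMap, GenomicInterval

__all__ = [
    "FourCProfile",
    "InteractionCall",
    "running_mean",
    "quantile_normalize",
    "estimate_background",
    "call_interactions",
    "conserved_calls",
    "profiles_from_counts",
    "DEFAULT_SMOOTH_WINDOW",
]

DEFAULT_SMOOTH_WINDOW = 21


@dataclass
class InteractionCall:
    interval: GenomicInterval
    score: float  # mean enrichment over background within the interval
    n_fragments: int = 0


@dataclass
class FourCProfile:
    """Raw, smoothed and normalized contact values for one sample."""

    fragmap: FragmentMap
    viewpoint: int  # fragment index
    raw: np.ndarray
    sample: str = "sample"
    mask: np.ndarray | None = None  # True at excluded (viewpoint-proximal) frags
    smoothed: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.fragmap):
            raise ValueError("raw counts length must equal fragment count")
        if self.mask is None:
            self.mask = np.zeros(len(self.raw), dtype=bool)

    def working_values(self) -> np.ndarray:
        """Normalized if present, else smoothed, else raw (mask applied)."""
        for v in (self.normalized, self.smoothed):
            if v is not None:
                return v
        v = self.raw.copy()
        v[self.mask] = np.nan
        return v


def mask_viewpoint(n: int, viewpoint: int, flank: int = 1) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[max(0, viewpoint - flank) : min(n, viewpoint + flank + 1)] = True
    return mask


def running_mean(
    values: np.ndarray,
    window: int = DEFAULT_SMOOTH_WINDOW,
    mask: np.ndarray | None = None,
    circular: bool = False,
) -> np.ndarray:
    """Centered running mean over an odd window.

    Masked (or NaN) positions are excluded from both numerator and
    denominator; window edges are truncated (or wrapped when
    ``circular``). Positions that are themselves masked stay NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(values, dtype=float).copy()
    if mask is not None:
        x[np.asarray(mask, dtype=bool)] = np.nan
    half = window // 2
    if circular:
        padded = np.concatenate([x[-half:], x, x[:half]])
        sm = (
            pd.Series(padded)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()[half : half + len(x)]
        )
    else:
        sm = pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    if mask is not None:
        sm[np.asarray(mask, dtype=bool)] = np.nan
    return sm


def quantile_normalize(
    vectors: Sequence[np.ndarray], mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """Joint quantile normalization of >= 2 equal-length vectors.

    Every sample's r-th order statistic is replaced by the mean of all
    samples' r-th order statistics; tied input values receive the mean
    of the target quantiles they span. Masked positions stay NaN and are
    excluded from the quantile computation (the mask is shared).
    """
    if len(vectors) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    n = len(vectors[0])
    for v in vectors:
        if len(v) != n:
            raise ValueError("all sample vectors must have equal length")
    X = np.column_stack([np.asarray(v, dtype=float) for v in vectors])
    valid = ~np.any(np.isnan(X), axis=1)
    if mask is not None:
        valid &= ~np.asarray(mask, dtype=bool)
    sub = X[valid]
    target = np.sort(sub, axis=0).mean(axis=1)
    out = []
    m = sub.shape[0]
    for k in range(X.shape[1]):
        col = sub[:, k]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(m)
        mapped[order] = target
        # ties: average the target quantiles each tied group spans
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=mapped)
        counts = np.bincount(inv)
        mapped = (sums / counts)[inv]
        full = np.full(n, np.nan)
        full[valid] = mapped
        out.append(full)
    return out


def estimate_background(
    values: np.ndarray,
    fragmap: FragmentMap,
    viewpoint: int,
    trim_fraction: float = 0.1,
) -> np.ndarray:
    """Monotone non-increasing background versus distance from the
    viewpoint, fitted per side by isotonic regression.

    A second pass refits after excluding the ``trim_fraction`` most
    enriched fragments, so planted peaks do not inflate the fit.
    """
    mids = fragmap.midpoints.astype(float)
    vp_mid = float(fragmap.midpoints[viewpoint])
    bg = np.full(len(values), np.nan)
    for side in (slice(0, viewpoint), slice(viewpoint + 1, len(values))):
        idx = np.arange(len(values))[side]
        if len(idx) == 0:
            continue
        dist = np.abs(mids[idx] - vp_mid)
        y = values[idx]
        ok = ~np.isnan(y)
        if ok.sum() < 2:
            continue
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        fit = iso.fit(dist[ok], y[ok]).predict(dist)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fit > 0, y / fit, np.nan)
        cutoff = np.nanquantile(ratio, 1.0 - trim_fraction)
        keep = ok & ~(ratio > cutoff)
        if keep.sum() >= 2:
            fit = iso.fit(dist[keep], y[keep]).predict(dist)
        bg[idx] = fit
    return bg


def call_interactions(
    profile: FourCProfile,
    background_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_quantile: float = 0.95,
    min_enrichment: float = 2.0,
) -> list[InteractionCall]:
    """Call interaction intervals from a smoothed/normalized profile.

    Enrichment is the profile over its per-side isotonic background.
    Fragments whose enrichment exceeds both the residual-quantile
    threshold and ``min_enrichment``, in runs of at least
    ``background_window // 3`` fragments, are merged into disjoint
    intervals with the mean enrichment attached. Scale-invariant:
    multiplying the profile by a positive constant leaves calls
    unchanged.
    """
    values = profile.working_values()
    vp = profile.viewpoint
    n = len(values)
    if vp < background_window and n - vp - 1 < background_window:
        raise ValueError("profile shorter than the background window on both sides")
    bg = estimate_background(values, profile.fragmap, vp)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(bg > 0, values / bg, np.nan)
    finite = enrich[np.isfinite(enrich)]
    if finite.size == 0:
        return []
    threshold = max(float(np.quantile(finite, threshold_quantile)), min_enrichment)
    if np.nanmax(finite) <= np.nanmin(finite) + 1e-12:
        return []  # flat residuals: nothing to call
    sig = np.zeros(n, dtype=bool)
    ok = np.isfinite(enrich)
    sig[ok] = enrich[ok] >= threshold
    min_run = max(1, background_window // 3)
    calls: list[InteractionCall] = []
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            b = profile.fragmap.boundaries
            calls.append(
                InteractionCall(
                    interval=GenomicInterval(
                        profile.fragmap.chrom, int(b[i]), int(b[j + 1])
                    ),
                    score=float(np.nanmean(enrich[i : j + 1])),
                    n_fragments=j - i + 1,
                )
            )
        i = j + 1
    return calls


def conserved_calls(
    call_sets: Sequence[Sequence[InteractionCall]],
) -> list[GenomicInterval]:
    """Intervals supported by every call set (intersection of
    pairwise-overlapping calls across all sets)."""
    if not call_sets:
        return []
    current = [c.interval for c in call_sets[0]]
    for calls in call_sets[1:]:
        nxt = []
        for iv in current:
            for c in calls:
                inter = iv.intersect(c.interval)
                if inter is not None:
                    nxt.append(inter)
        current = nxt
    return sorted(current)


def profiles_from_counts(
    counts: pd.DataFrame,
    fragmap: FragmentMap,
    viewpoint_pos: int,
    sample_names: Sequence[str] | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    mask_flank: int = 1,
) -> list[FourCProfile]:
    """Build smoothed, jointly quantile-normalized profiles from a
    per-fragment count table (one column per sample)."""
    if sample_names is None:
        sample_names = [
            c for c in counts.columns
            if c not in ("fragment_id", "chrom", "start", "end")
        ]
    vp = fragmap.fragment_at(viewpoint_pos)
    mask = mask_viewpoint(len(fragmap), vp, mask_flank)
    profiles = []
    for name in sample_names:
        prof = FourCProfile(
            fragmap=fragmap,
            viewpoint=vp,
            raw=counts[name].to_numpy(float),
            sample=str(name),
            mask=mask.copy(),
        )
        prof.smoothed = running_mean(prof.raw, smooth_window, mask=prof.mask)
        profiles.append(prof)
    if len(profiles) >= 2:
        normed = quantile_normalize([p.smoothed for p in profiles], mask=mask)
        for p, v in zip(profiles, normed):
            p.normalized = v
    return profiles
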