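"""Synthetic locus generator with ground truth for every pipeline stage.

The generator emulates a 2 Mb *Ikzf1*-like locus: a gene with alternative
first exons, 13 candidate DHS enhancers (6 truly active: 2 strong, 4
weak), six lymphoid transcription-factor peak sets of which all six bind
exactly one strong enhancer (the IkE120 analogue), a convergent CTCF
pair bracketing the regulatory domain, TAD structure with the enhancer
and promoter in one domain, an enhancer-promoter contact loop, and a 305
bp CRISPR deletion removing the enhancer in the mutant locus.

All simulators are deterministic given a :class:`numpy.random.Generator`
(or seed) and draw count noise from Poisson/multinomial models, the
standard first-order model for sequencing counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from enhancerscope.intervals import FragmentMap, GenomicInterval, SignalTrack

__all__ = [
    "LocusModel",
    "CapstarrParams",
    "HicParams",
    "FourCParams",
    "QpcrParams",
    "ChipParams",
    "SimulationConfig",
    "default_locus",
    "default_config",
    "simulate_sequence",
    "simulate_capstarr_counts",
    "expected_hic_matrix",
    "simulate_hic_matrix",
    "simulate_fourc_counts",
    "simulate_qpcr",
    "simulate_chip_tracks",
    "apply_deletion",
]


# ---------------------------------------------------------------------------
# Locus model


@dataclass
class LocusModel:
    """Coordinate-anchored ground truth of the synthetic locus."""

    chrom: str
    chrom_length: int
    gene: GenomicInterval
    exons: list[GenomicInterval]
    promoter: GenomicInterval
    dhs_list: list[GenomicInterval]
    true_fc: dict[str, float]
    tf_peak_sets: dict[str, list[GenomicInterval]]
    ctcf_sites: list[GenomicInterval]
    tad_boundaries_bp: list[int]
    loop_anchors_bp: list[tuple[int, int]]
    enhancer_truth: list[str]
    ike120_name: str
    viewpoint_pos: int
    deletion: GenomicInterval | None = None

    def __post_init__(self) -> None:
        for iv in self.all_features():
            if iv.end > self.chrom_length:
                raise ValueError(f"feature {iv.name} extends past the chromosome")
        names = [d.name for d in self.dhs_list]
        if len(set(names)) != len(names):
            raise ValueError("DHS names must be unique")

    def all_features(self) -> list[GenomicInterval]:
        feats = [self.gene, self.promoter, *self.exons, *self.dhs_list,
                 *self.ctcf_sites]
        for peaks in self.tf_peak_sets.values():
            feats.extend(peaks)
        return feats

    def dhs_by_name(self, name: str) -> GenomicInterval:
        for d in self.dhs_list:
            if d.name == name:
                return d
        raise KeyError(name)

    def n_bins(self, bin_size: int) -> int:
        return -(-self.chrom_length // bin_size)

    def tad_boundary_bins(self, bin_size: int) -> list[int]:
        return sorted({bp // bin_size for bp in self.tad_boundaries_bp})


def default_locus(seed: int = 0) -> LocusModel:
    """The default 2 Mb fixture: 13 DHSs, 6 active (2 strong + 4 weak).

    The IkE120 analogue sits 120 kb upstream of the promoter, is bound
    by all six TF peak sets, lies between a convergent CTCF pair, loops
    to the promoter, and is covered by a 305 bp deletion in the mutant.
    """
    chrom = "chrS"
    length = 2_000_000
    gene_start = 1_450_000
    gene = GenomicInterval(chrom, gene_start, 1_520_000, "Ikzf1_syn", strand="+")
    exons = [
        GenomicInterval(chrom, gene_start, gene_start + 500, "E1L", strand="+"),
        GenomicInterval(chrom, gene_start + 8_000, gene_start + 8_300, "E1S", strand="+"),
        GenomicInterval(chrom, gene_start + 20_000, gene_start + 20_200, "E3", strand="+"),
        GenomicInterval(chrom, gene_start + 30_000, gene_start + 30_180, "E4", strand="+"),
        GenomicInterval(chrom, gene_start + 40_000, gene_start + 40_150, "E5", strand="+"),
        GenomicInterval(chrom, gene_start + 50_000, gene_start + 50_140, "E6", strand="+"),
        GenomicInterval(chrom, gene_start + 58_000, gene_start + 58_200, "E7", strand="+"),
        GenomicInterval(chrom, gene_start + 65_000, gene_start + 68_000, "E8", strand="+"),
    ]
    promoter = GenomicInterval(chrom, gene_start - 1_000, gene_start + 1_000, "promoter")

    half = 125  # DHS half-width (250 bp open-chromatin sites)
    census: list[tuple[str, int, float]] = [
        ("D-270", 1_180_000, 1.0),
        ("D-230", 1_220_000, 0.9),
        ("IkE180", 1_270_000, 3.8),
        ("D-150", 1_300_000, 1.1),
        ("IkE120", 1_330_000, 4.5),
        ("D-90", 1_360_000, 2.0),
        ("D-60", 1_390_000, 1.2),
        ("D-40", 1_410_000, 1.8),
        ("D-20", 1_430_000, 1.0),
        ("IkE+15", 1_465_000, 2.6),
        ("D+50", 1_500_000, 2.3),
        ("D+90", 1_540_000, 1.0),
        ("D+130", 1_580_000, 1.1),
    ]
    dhs_list = [
        GenomicInterval(chrom, c - half, c + half, name, score=fc)
        for name, c, fc in census
    ]
    true_fc = {name: fc for name, _, fc in census}
    active = [n for n, fc in true_fc.items() if fc >= 1.5]

    # Six lymphoid TF peak sets: all six cover IkE120; fewer elsewhere.
    factors = ["Ikaros", "Runx1", "Gata3", "Tcf1", "Ets1", "Satb1"]
    ike120 = dhs_list[4]
    ike180 = dhs_list[2]
    ike15 = dhs_list[9]
    tf_peak_sets: dict[str, list[GenomicInterval]] = {}
    for i, f in enumerate(factors):
        peaks = [GenomicInterval(chrom, ike120.start - 50, ike120.end + 50, f)]
        if i < 3:
            peaks.append(GenomicInterval(chrom, ike180.start - 50, ike180.end + 50, f))
        if i < 2:
            peaks.append(GenomicInterval(chrom, ike15.start - 50, ike15.end + 50, f))
        # decoy peak far from any DHS
        peaks.append(GenomicInterval(chrom, 700_000 + i * 10_000, 700_400 + i * 10_000, f))
        tf_peak_sets[f] = sorted(peaks)

    ctcf_sites = [
        GenomicInterval(chrom, 199_900, 200_100, "CTCF_a", strand="+"),
        GenomicInterval(chrom, 399_900, 400_100, "CTCF_b", strand="+"),
        GenomicInterval(chrom, 1_149_900, 1_150_100, "CTCF_c", strand="-"),
        GenomicInterval(chrom, 1_249_900, 1_250_100, "CTCF_fwd", strand="+"),
        GenomicInterval(chrom, 1_559_900, 1_560_100, "CTCF_rev", strand="-"),
    ]

    # TAD boundaries aligned with the convergent CTCF pair; the enhancer
    # (bin 133 at 10 kb) and promoter (bin 145) share the middle domain.
    tad_boundaries_bp = [600_000, 1_250_000, 1_560_000]
    loop_anchors_bp = [(ike120.midpoint, promoter.midpoint)]

    deletion = GenomicInterval(chrom, 1_329_848, 1_330_153, "dIkE120")  # 305 bp
    assert deletion.width == 305 and deletion.start < ike120.start
    assert deletion.end > ike120.end

    return LocusModel(
        chrom=chrom,
        chrom_length=length,
        gene=gene,
        exons=exons,
        promoter=promoter,
        dhs_list=dhs_list,
        true_fc=true_fc,
        tf_peak_sets=tf_peak_sets,
        ctcf_sites=ctcf_sites,
        tad_boundaries_bp=tad_boundaries_bp,
        loop_anchors_bp=loop_anchors_bp,
        enhancer_truth=active,
        ike120_name="IkE120",
        viewpoint_pos=gene_start - 1_200,
        deletion=deletion,
    )


# ---------------------------------------------------------------------------
# Simulation parameters


@dataclass
class CapstarrParams:
    """Reporter-screen count model: input ~ multinomial over fragment
    lengths, screen ~ multinomial over length x true fold-change."""

    depth: int = 1_000_000
    n_replicates: int = 2
    background_fragment_bp: int = 1_000
    cloned_fragment_bp: int = 500  # reporter insert centered on the DHS


@dataclass
class HicParams:
    bin_size: int = 10_000
    base_contacts: float = 200.0
    decay_exponent: float = 1.0
    within_tad_factor: float = 3.0
    loop_bonus: float = 4.0
    poisson_noise: bool = True


@dataclass
class FourCParams:
    """Viewpoint-anchored contact counts: hyperbolic distance decay times
    a planted enrichment over the true enhancer intervals."""

    scale: float = 40.0
    decay_tau: float = 50_000.0
    enrichment: float = 5.0
    peak_halfwidth: int = 2_000
    mask_flank: int = 1
    sample_names: tuple[str, ...] = ("rep1", "rep2")
    poisson_noise: bool = True


@dataclass
class QpcrParams:
    ct_sd: float = 0.1
    n_replicates: int = 3
    housekeeping: str = "Rpl32"
    baseline_hk_ct: float = 20.0
    baseline_target_ct: float = 25.0
    # expression relative to the wt unstimulated reference; None -> defaults
    expression: dict[tuple[str, str], float] | None = None


@dataclass
class ChipParams:
    bin_bp: int = 50
    baseline: float = 1.0
    height_per_fc: float = 2.0
    peak_sd_bp: float = 300.0
    noise_sd: float = 0.05


@dataclass
class SimulationConfig:
    capstarr: CapstarrParams = field(default_factory=CapstarrParams)
    hic: HicParams = field(default_factory=HicParams)
    fourc: FourCParams = field(default_factory=FourCParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    chip: ChipParams = field(default_factory=ChipParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capstarr.depth < 0:
            raise ValueError("sequencing depth must be non-negative")
        if self.qpcr.n_replicates < 2:
            raise ValueError("need >= 2 qPCR replicates")


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def _rng(rng_or_seed: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# ---------------------------------------------------------------------------
# Sequence


def simulate_sequence(length: int, rng: np.random.Generator | int = 0) -> str:
    """Uniform-composition random nucleotide sequence (GATC sites occur
    about every 256 bp, giving a realistic DpnII fragment map)."""
    r = _rng(rng)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[r.integers(0, 4, size=length)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# CapStarr-seq counts


def capstarr_fragments(
    model: LocusModel, background_bp: int = 1_000, cloned_bp: int = 500
) -> pd.DataFrame:
    """Fragment universe of the reporter screen.

    Each candidate DHS is represented by one cloned reporter fragment of
    ``cloned_bp`` centered on the DHS; background tiles with unit
    fold-change fill the rest of the chromosome."""
    rows = []
    dhs_sorted = sorted(model.dhs_list, key=lambda d: d.start)
    cursor = 0
    for d in dhs_sorted:
        half = cloned_bp // 2
        fs, fe = max(0, d.midpoint - half), min(model.chrom_length, d.midpoint + half)
        pos = cursor
        while pos < fs:
            end = min(pos + background_bp, fs)
            if end - pos >= 100:  # skip slivers
                rows.append(("bg_%d" % pos, pos, end, 1.0))
            pos = end
        rows.append((d.name, fs, fe, model.true_fc[d.name]))
        cursor = fe
    pos = cursor
    while pos < model.chrom_length:
        end = min(pos + background_bp, model.chrom_length)
        if end - pos >= 100:
            rows.append(("bg_%d" % pos, pos, end, 1.0))
        pos = end
    df = pd.DataFrame(rows, columns=["fragment_id", "start", "end", "true_fc"])
    df.insert(1, "chrom", model.chrom)
    return df


def simulate_capstarr_counts(
    model: LocusModel,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[pd.DataFrame]:
    """One count table per replicate with screen and input counts.

    Input counts are multinomial with probability proportional to
    fragment length; screen counts proportional to length x true
    fold-change, so the expected FPKM ratio recovers the true FC (up to
    the negligible renormalization by the background-dominated mean FC).
    """
    p = config.capstarr
    r = _rng(config.seed if rng is None else rng)
    frags = capstarr_fragments(model, p.background_fragment_bp, p.cloned_fragment_bp)
    lengths = (frags["end"] - frags["start"]).to_numpy(float)
    w_input = lengths / lengths.sum()
    w_screen = lengths * frags["true_fc"].to_numpy(float)
    w_screen = w_screen / w_screen.sum()
    out = []
    for _ in range(p.n_replicates):
        df = frags[["fragment_id", "chrom", "start", "end"]].copy()
        if p.depth > 0:
            df["screen_count"] = r.multinomial(p.depth, w_screen)
            df["input_count"] = r.multinomial(p.depth, w_input)
        else:
            df["screen_count"] = 0
            df["input_count"] = 0
        out.append(df)
    return out


# ---------------------------------------------------------------------------
# Hi-C


def expected_hic_matrix(model: LocusModel, params: HicParams) -> np.ndarray:
    """Expected contact counts: power-law distance decay x within-TAD
    enrichment x loop bonus at configured anchor pairs. Symmetric."""
    n = model.n_bins(params.bin_size)
    idx = np.arange(n)
    boundaries = model.tad_boundary_bins(params.bin_size)
    block = np.searchsorted(boundaries, idx, side="right")
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = params.base_contacts * (1.0 + dist) ** (-params.decay_exponent)
    expected *= np.where(block[:, None] == block[None, :], params.within_tad_factor, 1.0)
    for a_bp, b_bp in model.loop_anchors_bp:
        i, j = a_bp // params.bin_size, b_bp // params.bin_size
        expected[i, j] *= params.loop_bonus
        expected[j, i] *= params.loop_bonus
    return expected


def simulate_hic_matrix(
    model: LocusModel,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> "np.ndarray":
    """Poisson-sampled symmetric contact matrix (raw counts)."""
    p = config.hic
    r = _rng(config.seed if rng is None else rng)
    expected = expected_hic_matrix(model, p)
    if not p.poisson_noise:
        return expected
    n = expected.shape[0]
    upper = np.triu_indices(n)
    counts = np.zeros_like(expected)
    counts[upper] = r.poisson(expected[upper])
    counts = counts + np.triu(counts, 1).T
    return counts


# ---------------------------------------------------------------------------
# 4C


def expected_fourc(
    model: LocusModel, params: FourCParams, fragmap: FragmentMap
) -> np.ndarray:
    mids = fragmap.midpoints.astype(float)
    dist = np.abs(mids - model.viewpoint_pos)
    expected = params.scale / (1.0 + dist / params.decay_tau)
    for name in model.enhancer_truth:
        d = model.dhs_by_name(name)
        lo, hi = d.midpoint - params.peak_halfwidth, d.midpoint + params.peak_halfwidth
        expected[(mids >= lo) & (mids < hi)] *= params.enrichment
    return expected


def simulate_fourc_counts(
    model: LocusModel,
    config: SimulationConfig,
    fragmap: FragmentMap,
    rng: np.random.Generator | int | None = None,
    planted_peaks: bool = True,
) -> pd.DataFrame:
    """Per-fragment 4C counts, one column per sample.

    Counts at the viewpoint fragment and ``mask_flank`` neighbours per
    side are zeroed (self-ligation/undigested artifacts dominate there).
    """
    p = config.fourc
    r = _rng(config.seed if rng is None else rng)
    if planted_peaks:
        expected = expected_fourc(model, p, fragmap)
    else:
        mids = fragmap.midpoints.astype(float)
        expected = p.scale / (1.0 + np.abs(mids - model.viewpoint_pos) / p.decay_tau)
    vp = fragmap.fragment_at(model.viewpoint_pos)
    data = {
        "fragment_id": [f"frag_{i}" for i in range(len(fragmap))],
        "chrom": fragmap.chrom,
        "start": fragmap.boundaries[:-1],
        "end": fragmap.boundaries[1:],
    }
    lo = max(0, vp - p.mask_flank)
    hi = min(len(fragmap), vp + p.mask_flank + 1)
    for name in p.sample_names:
        counts = r.poisson(expected) if p.poisson_noise else expected.copy()
        counts[lo:hi] = 0
        data[name] = counts
    df = pd.DataFrame(data)
    df.attrs["viewpoint_fragment"] = vp
    return df


# ---------------------------------------------------------------------------
# qPCR


def default_expression() -> dict[tuple[str, str], float]:
    """True expression per (group, amplicon) relative to wt unstimulated.

    Encodes the study's effect sizes: the common 3' exon (E8) and E4-E5
    junctions drop four-fold in the enhancer-deleted clone, E3-E4 and
    E6-E7 two-fold; both alternative promoters are reduced (E1L more);
    eRNA around the enhancer is strongly reduced; the ~3x stimulation
    response of E8 is abolished in the mutant.
    """
    amplicons = {
        "E8": 0.25,
        "E4-E5": 0.25,
        "E3-E4": 0.5,
        "E6-E7": 0.5,
        "E1L": 0.2,
        "E1S": 0.4,
        "eRNA-set1": 0.15,
        "eRNA-set2": 0.2,
    }
    expr: dict[tuple[str, str], float] = {}
    for amp, mut_expr in amplicons.items():
        expr[("wt_unstim", amp)] = 1.0
        expr[("dIkE120_unstim", amp)] = mut_expr
        induction = 3.0 if amp in ("E8", "eRNA-set1", "eRNA-set2") else 1.0
        expr[("wt_stim", amp)] = induction
        expr[("dIkE120_stim", amp)] = mut_expr  # induction abolished
    return expr


def simulate_qpcr(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Tidy Ct table (group, amplicon, replicate, ct).

    Ct(target) = baseline - log2(expression) + N(0, sd); the
    housekeeping gene has constant expected Ct across groups, so only Ct
    differences are meaningful.
    """
    p = config.qpcr
    r = _rng(config.seed if rng is None else rng)
    expr = p.expression if p.expression is not None else default_expression()
    for e in expr.values():
        if e <= 0:
            raise ValueError("true expression levels must be positive")
    groups = sorted({g for g, _ in expr})
    rows = []
    for g in groups:
        for rep in range(1, p.n_replicates + 1):
            ct_hk = p.baseline_hk_ct + r.normal(0.0, p.ct_sd)
            rows.append((g, p.housekeeping, rep, ct_hk))
        for (gg, amp), e in expr.items():
            if gg != g:
                continue
            for rep in range(1, p.n_replicates + 1):
                ct = p.baseline_target_ct - np.log2(e) + r.normal(0.0, p.ct_sd)
                rows.append((g, amp, rep, ct))
    return pd.DataFrame(rows, columns=["group", "amplicon", "replicate", "ct"])


# ---------------------------------------------------------------------------
# ChIP coverage tracks


def _chip_values(model: LocusModel, params: ChipParams, rng: np.random.Generator,
                 length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nbin = -(-length // params.bin_bp)
    starts = np.arange(nbin, dtype=np.int64) * params.bin_bp
    ends = np.minimum(starts + params.bin_bp, length)
    mids = (starts + ends) / 2.0
    vals = np.full(nbin, params.baseline, dtype=float)
    for d in model.dhs_list:
        fc = model.true_fc[d.name]
        if fc < 1.5:
            continue
        amp = params.height_per_fc * fc
        vals += amp * np.exp(-0.5 * ((mids - d.midpoint) / params.peak_sd_bp) ** 2)
    if params.noise_sd > 0:
        vals = np.clip(vals + rng.normal(0.0, params.noise_sd, size=nbin), 0.0, None)
    return starts, ends, vals


def simulate_chip_tracks(
    model: LocusModel,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[SignalTrack, SignalTrack]:
    """Paired H3K27ac-like coverage: wt track (wt coordinates) and mutant
    track (mutant coordinates, the deleted enhancer's peak absent)."""
    r = _rng(config.seed if rng is None else rng)
    mutant = apply_deletion(model)
    ws, we, wv = _chip_values(model, config.chip, r, model.chrom_length)
    ms, me, mv = _chip_values(mutant, config.chip, r, mutant.chrom_length)
    return (
        SignalTrack(model.chrom, ws, we, wv),
        SignalTrack(mutant.chrom, ms, me, mv),
    )


# ---------------------------------------------------------------------------
# Deletion geometry


def _lift_interval(
    iv: GenomicInterval, deletion: GenomicInterval
) -> GenomicInterval | None:
    """Map a wt-coordinate interval into the deleted chromosome.

    Features fully inside the deletion vanish; partial overlaps are
    truncated; features downstream shift left by the deletion width.
    """
    w = deletion.width
    if iv.end <= deletion.start:
        return iv
    if iv.start >= deletion.end:
        return iv.shift(-w)
    if iv.start >= deletion.start and iv.end <= deletion.end:
        return None
    if iv.start < deletion.start and iv.end > deletion.end:
        return replace(iv, end=iv.end - w)
    if iv.start < deletion.start:
        return replace(iv, end=deletion.start)
    return replace(iv, start=deletion.start, end=iv.end - w)


def _lift_pos(pos: int, deletion: GenomicInterval) -> int:
    if pos < deletion.start:
        return pos
    if pos >= deletion.end:
        return pos - deletion.width
    raise ValueError("position falls inside the deletion")


def apply_deletion(model: LocusModel) -> LocusModel:
    """Mutant locus with the configured deletion excised.

    Coordinates downstream of the deletion shift left by its width;
    features fully inside it are removed. Deletions overlapping the gene
    body or the 4C viewpoint are refused (unsupported scenario).
    """
    d = model.deletion if model.deletion is not None else _default_deletion(model)
    if d is None:
        raise ValueError("locus model has no deletion configured")
    if d.overlaps(model.gene):
        raise ValueError("deletion overlapping the gene body is unsupported")
    if d.start <= model.viewpoint_pos < d.end:
        raise ValueError("deletion overlapping the 4C viewpoint is unsupported")

    def lift_list(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
        out = []
        for iv in ivs:
            lifted = _lift_interval(iv, d)
            if lifted is not None:
                out.append(lifted)
        return out

    dhs = lift_list(model.dhs_list)
    kept = {x.name for x in dhs}
    return LocusModel(
        chrom=model.chrom,
        chrom_length=model.chrom_length - d.width,
        gene=_lift_interval(model.gene, d),
        exons=lift_list(model.exons),
        promoter=_lift_interval(model.promoter, d) or model.promoter,
        dhs_list=dhs,
        true_fc={k: v for k, v in model.true_fc.items() if k in kept},
        tf_peak_sets={f: lift_list(p) for f, p in model.tf_peak_sets.items()},
        ctcf_sites=lift_list(model.ctcf_sites),
        tad_boundaries_bp=[_lift_pos(b, d) for b in model.tad_boundaries_bp],
        loop_anchors_bp=[
            (_lift_pos(a, d) if not (d.start <= a < d.end) else d.start,
             _lift_pos(b, d) if not (d.start <= b < d.end) else d.start)
            for a, b in model.loop_anchors_bp
        ],
        enhancer_truth=[n for n in model.enhancer_truth if n in kept],
        ike120_name=model.ike120_name,
        viewpoint_pos=_lift_pos(model.viewpoint_pos, d),
        deletion=None,
    )


def _default_deletion(model: LocusModel) -> GenomicInterval | None:
    return None
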