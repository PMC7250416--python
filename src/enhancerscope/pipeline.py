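"""End-to-end orchestration: simulate -> activity -> topology -> 4C ->
prioritize -> qPCR, with a manifest recording parameters, seeds and
output checksums.

A single global seed is fanned out per stage by hashing the stage name,
so each stage is independently reproducible and re-running the pipeline
with the same configuration yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from enhancerscope import capstarr, fourc, hic, prioritize, qpcr
from enhancerscope.intervals import (
    GenomicInterval,
    digest,
    write_bed,
    write_bed9_rgb,
    write_bedgraph,
)
from enhancerscope.simulate import (
    default_config,
    default_locus,
    simulate_capstarr_counts,
    simulate_chip_tracks,
    simulate_fourc_counts,
    simulate_hic_matrix,
    simulate_qpcr,
    simulate_sequence,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) % (2**31)


@dataclass
class RunConfig:
    """Pipeline parameters; unspecified values resolve to the study
    defaults (thresholds 1.5/3, top fraction 0.05, 10 kb bins, window 10
    bins, flank 3, strength 0.7, smoothing window 21)."""

    outdir: str = "enhancerscope_run"
    seed: int = 0
    weak_threshold: float = capstarr.WEAK_THRESHOLD
    strong_threshold: float = capstarr.STRONG_THRESHOLD
    top_fraction: float = capstarr.TOP_FRACTION
    bin_size: int = 10_000
    window_bins: int = hic.DEFAULT_WINDOW_BINS
    flank_bins: int = hic.DEFAULT_FLANK_BINS
    strength_threshold: float = hic.DEFAULT_STRENGTH_THRESHOLD
    smooth_window: int = fourc.DEFAULT_SMOOTH_WINDOW
    threshold_quantile: float = 0.95
    housekeeping: str = qpcr.DEFAULT_HOUSEKEEPING
    sequence_length: int | None = None  # None -> locus chrom_length


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | None = None) -> dict[str, str]:
    """Run every stage on the default synthetic locus; returns the
    manifest (also written as TSV key-value pairs in the output dir)."""
    cfg = config or RunConfig()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {"seed": str(cfg.seed)}
    for key in ("weak_threshold", "strong_threshold", "top_fraction", "bin_size",
                "window_bins", "flank_bins", "strength_threshold", "smooth_window",
                "threshold_quantile", "housekeeping"):
        manifest[f"param.{key}"] = str(getattr(cfg, key))

    stage = "simulate"
    try:
        model = default_locus()
        sim = default_config(seed=stage_seed(cfg.seed, "simulate"))
        sim.hic.bin_size = cfg.bin_size
        write_bed(model.dhs_list, out / "dhs.bed")
        write_bed(model.ctcf_sites, out / "ctcf.bed")
        tf_bed = [p for peaks in model.tf_peak_sets.values() for p in peaks]
        write_bed(sorted(tf_bed), out / "tf_peaks.bed")
        manifest[f"seed.{stage}"] = str(sim.seed)

        stage = "capstarr"
        rng = np.random.default_rng(stage_seed(cfg.seed, "capstarr"))
        tables = simulate_capstarr_counts(model, sim, rng)
        for i, t in enumerate(tables, 1):
            t.to_csv(out / f"capstarr_rep{i}.tsv", sep="\t", index=False)
        records = capstarr.records_from_counts(
            tables,
            dhs_names=[d.name for d in model.dhs_list],
            weak_threshold=cfg.weak_threshold,
            strong_threshold=cfg.strong_threshold,
            top_fraction=cfg.top_fraction,
        )
        capstarr.activity_table(records).to_csv(
            out / "activity.tsv", sep="\t", index=False
        )
        colored = [
            GenomicInterval(r.dhs.chrom, r.dhs.start, r.dhs.end, r.dhs.name,
                            score=round(r.fc, 4) if r.fc is not None else 0.0)
            for r in records
        ]
        write_bed9_rgb(colored, out / "activity_rgb.bed")

        stage = "hic"
        rng = np.random.default_rng(stage_seed(cfg.seed, "hic"))
        counts = simulate_hic_matrix(model, sim, rng)
        raw = hic.ContactMatrix(model.chrom, cfg.bin_size, counts)
        hic.write_dense_matrix(raw, out / "hic_raw.tsv")
        balanced = hic.kr_balance(raw)
        profile = hic.insulation_scores(balanced, cfg.window_bins)
        profile.flank_bins = cfg.flank_bins
        profile.strength_threshold = cfg.strength_threshold
        profile = hic.call_boundaries(profile)
        write_bedgraph(profile.to_track(), out / "insulation.bedgraph")
        write_bed(
            [balanced.bin_interval(b) for b in profile.boundaries],
            out / "tad_boundaries.bed",
        )
        v4c = hic.virtual_4c(
            balanced, GenomicInterval(model.chrom, model.promoter.midpoint,
                                      model.promoter.midpoint + 1)
        )
        write_bedgraph(v4c, out / "virtual4c_promoter.bedgraph")

        stage = "fourc"
        rng = np.random.default_rng(stage_seed(cfg.seed, "fourc"))
        seq = simulate_sequence(
            cfg.sequence_length or model.chrom_length,
            np.random.default_rng(stage_seed(cfg.seed, "sequence")),
        )
        (out / "chromosome.fa").write_text(f">{model.chrom}\n{seq}\n")
        fragmap = digest(seq, "GATC", model.chrom)
        fc_counts = simulate_fourc_counts(model, sim, fragmap, rng)
        fc_counts.to_csv(out / "fourc_counts.tsv", sep="\t", index=False)
        profiles = fourc.profiles_from_counts(
            fc_counts, fragmap, model.viewpoint_pos,
            smooth_window=cfg.smooth_window, mask_flank=sim.fourc.mask_flank,
        )
        call_sets = [
            fourc.call_interactions(p, cfg.smooth_window, cfg.threshold_quantile)
            for p in profiles
        ]
        conserved = fourc.conserved_calls(call_sets)
        write_bed(conserved, out / "fourc_conserved_calls.bed")
        for p in profiles:
            track = hic.SignalTrack(
                fragmap.chrom, fragmap.boundaries[:-1], fragmap.boundaries[1:],
                p.normalized if p.normalized is not None else p.smoothed,
            )
            write_bedgraph(track, out / f"fourc_{p.sample}.bedgraph")

        stage = "prioritize"
        reports = prioritize.prioritize(
            records, model.tf_peak_sets, model.ctcf_sites,
            contact_track=v4c,
            interaction_calls=conserved,
        )
        prioritize.report_table(reports).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )

        stage = "qpcr"
        rng = np.random.default_rng(stage_seed(cfg.seed, "qpcr"))
        ct = simulate_qpcr(sim, rng)
        ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        results = []
        for amp in sorted({a for a in ct["amplicon"] if a != cfg.housekeeping}):
            results.append(
                qpcr.relative_expression(
                    ct, amp, "dIkE120_unstim", "wt_unstim", cfg.housekeeping
                )
            )
        rows = [
            (r.amplicon, r.relative_expression, r.sd, r.t_statistic, r.p_value,
             r.n_replicates)
            for r in results
        ]
        import pandas as pd

        pd.DataFrame(
            rows,
            columns=["amplicon", "relative_expression", "sd", "t", "p", "n"],
        ).to_csv(out / "expression.tsv", sep="\t", index=False)

        stage = "chip"
        rng = np.random.default_rng(stage_seed(cfg.seed, "chip"))
        wt_track, mut_track = simulate_chip_tracks(model, sim, rng)
        write_bedgraph(wt_track, out / "h3k27ac_wt.bedgraph")
        write_bedgraph(mut_track, out / "h3k27ac_mut.bedgraph")
        diff = qpcr.differential_track(wt_track, mut_track, model.deletion)
        write_bedgraph(diff, out / "h3k27ac_diff.bedgraph")
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        _write_manifest(manifest, out / "manifest.tsv")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["status"] = "completed"
    for f in sorted(out.iterdir()):
        if f.name != "manifest.tsv" and f.is_file():
            manifest[f"sha256.{f.name}"] = _sha256(f)
    _write_manifest(manifest, out / "manifest.tsv")
    return manifest


def _write_manifest(manifest: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")
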