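"""End-to-end orchestration: read -> filter -> statistics -> scan -> regions.

Both association tracks are run side by side:

* SNP-index track: filter, per-site dSNPindex, windowed mean fit, and a
  Monte-Carlo null envelope (90/95/99% by default); regions are windows
  above the 99% envelope.
* ED track: filter, per-site ED^k (k = 2 by default), distance-weighted
  window fit, and the genome-wide median + 3 SD threshold (the default
  region rule). The 99% fitted-value quantile is also computed and can be
  used to refine broad significant regions down to their summits
  (``ed_threshold_rule='quantile_99'`` or ``'refined'`` = must clear both);
  refinement trades region coverage of the causal locus for narrowness, so
  the wider median+3SD regions remain the default candidate set.

Windows holding fewer than ``min_sites_per_window`` retained SNPs are
treated as missing for thresholding and region calling: truncated
chromosome-tail windows and coverage dropouts otherwise contribute
single-site noise that both statistics inherit simultaneously.

The intersection of the two tracks' regions is the final candidate set.
Everything is deterministic under a fixed seed; each stage draws from its
own RNG stream spawned from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .io import (BulkSite, GeneInterval, read_bulk_vcf, read_gene_intervals,
                 write_regions_bed, write_regions_tsv)
from .filters import FilterLedger, apply_filters
from .stats import statistics_frame
from .scan import (ScanTrack, ThresholdSet, ed_threshold_median_sd,
                   ed_threshold_quantile, fit_track, make_windows,
                   null_envelope_delta)
from .regions import AssociationRegion, call_regions, intersect_tracks

__all__ = ["ScanParams", "PipelineConfig", "TrackResult", "ScanResult",
           "run_tracks", "run_full_scan"]


@dataclass(frozen=True)
class ScanParams:
    """Scan-stage knobs shared by both tracks."""

    window_bp: int = 1_000_000
    step_bp: int = 10_000
    fit_delta: str = "mean"
    fit_ed: str = "distance_weighted"
    ed_exponent: float = 2.0
    envelope_levels: tuple[float, ...] = (0.90, 0.95, 0.99)
    envelope_level_used: float = 0.99
    envelope_reps: int = 100_000
    ed_threshold_rule: str = "median_plus_3sd"  # | quantile_99 | refined
    ed_quantile: float = 0.99
    ed_n_sd: float = 3.0
    min_sites_per_window: int = 10

    def __post_init__(self) -> None:
        if self.window_bp < self.step_bp:
            raise ValueError("window must be >= step")
        if any(not 0 < q < 1 for q in self.envelope_levels):
            raise ValueError("envelope levels must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """Run configuration, loadable from YAML."""

    vcf: str
    out_dir: str
    gff: str | None = None
    samples: dict[str, str] = field(default_factory=lambda: {
        "parent_L": "parent_L", "parent_S": "parent_S",
        "bulk_L": "bulk_L", "bulk_S": "bulk_S"})
    chrom_lengths: dict[str, int] | None = None
    bulk_size: int = 50
    scan: ScanParams = field(default_factory=ScanParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scan = ScanParams(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in raw.pop("scan", {}).items()})
        return cls(scan=scan, **raw)


@dataclass
class TrackResult:
    ledger: FilterLedger
    tracks: dict[str, ScanTrack]  # per chromosome
    thresholds: dict[str, ThresholdSet]
    regions: list[AssociationRegion]
    region_threshold: float


@dataclass
class ScanResult:
    snp_index: TrackResult
    ed: TrackResult
    intersection: list[AssociationRegion]
    params: ScanParams = field(default_factory=ScanParams)

    def argmax_window(self, which: str) -> tuple[str, int] | None:
        """(chrom, window start) of the highest fitted value of a track.

        |delta| is maximised for the SNP-index track, fitted ED^k for the ED
        track; windows below the minimum site count are ineligible.
        """
        tr = self.snp_index if which == "snp_index" else self.ed
        best: tuple[str, int] | None = None
        best_val = -np.inf
        for chrom, track in tr.tracks.items():
            masked = _mask_sparse(track, self.params.min_sites_per_window)
            vals = masked.fitted if which == "ed" else np.abs(masked.fitted)
            if np.all(np.isnan(vals)):
                continue
            w = int(np.nanargmax(vals))
            if vals[w] > best_val:
                best_val = vals[w]
                best = (chrom, int(track.window_starts[w]))
        return best


def _mask_sparse(track: ScanTrack, min_sites: int) -> ScanTrack:
    """View of a track with under-populated windows marked missing."""
    sparse = track.n_sites < min_sites
    fitted = track.fitted.copy()
    fitted[sparse] = np.nan
    n_sites = track.n_sites.copy()
    n_sites[sparse] = 0
    return ScanTrack(chrom=track.chrom, window_size_bp=track.window_size_bp,
                     step_bp=track.step_bp, window_starts=track.window_starts,
                     window_ends=track.window_ends, fitted=fitted,
                     n_sites=n_sites, statistic=track.statistic)


def _infer_chrom_lengths(sites: Sequence[BulkSite]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for s in sites:
        lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.pos)
    return lengths


def run_tracks(sites: Sequence[BulkSite], params: ScanParams = ScanParams(),
               chrom_lengths: Mapping[str, int] | None = None,
               bulk_size: int = 50, seed: int = 0) -> ScanResult:
    """Run both association tracks on in-memory sites and intersect them."""
    if chrom_lengths is None:
        chrom_lengths = _infer_chrom_lengths(sites)
    rng_envelope = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    # --- SNP-index track ---------------------------------------------------
    kept_si, ledger_si = apply_filters(sites, "snp_index")
    stats_si = statistics_frame(kept_si, k=params.ed_exponent)
    mean_depth_aa = max(1, round(float(np.mean(
        [s.Laa + s.Saa for s in kept_si])))) if kept_si else 1
    mean_depth_ab = max(1, round(float(np.mean(
        [s.Lab + s.Sab for s in kept_si])))) if kept_si else 1
    envelope = null_envelope_delta(mean_depth_aa, mean_depth_ab, bulk_size,
                                   levels=params.envelope_levels,
                                   reps=params.envelope_reps, rng=rng_envelope)
    delta_threshold = envelope.at(params.envelope_level_used)

    tracks_si: dict[str, ScanTrack] = {}
    regions_si: list[AssociationRegion] = []
    for chrom, length in chrom_lengths.items():
        sub = stats_si[stats_si.chrom == chrom]
        windows = make_windows(length, params.window_bp, params.step_bp)
        track = fit_track(sub.pos.to_numpy(), sub.delta_snp_index.to_numpy(),
                          chrom, windows, "delta_snp_index",
                          fit_method=params.fit_delta,
                          window_size=params.window_bp, step=params.step_bp)
        tracks_si[chrom] = track
        # two-sided: a locus can push delta toward +1 or -1
        masked = _mask_sparse(track, params.min_sites_per_window)
        abs_track = ScanTrack(chrom=chrom, window_size_bp=masked.window_size_bp,
                              step_bp=masked.step_bp,
                              window_starts=masked.window_starts,
                              window_ends=masked.window_ends,
                              fitted=np.abs(masked.fitted),
                              n_sites=masked.n_sites,
                              statistic="delta_snp_index")
        regions_si.extend(call_regions(abs_track, delta_threshold, "snp_index"))
    result_si = TrackResult(ledger=ledger_si, tracks=tracks_si,
                            thresholds={"null_envelope": envelope},
                            regions=regions_si,
                            region_threshold=delta_threshold)

    # --- ED track ------------------------------------------------------------
    kept_ed, ledger_ed = apply_filters(sites, "ed")
    stats_ed = statistics_frame(kept_ed, k=params.ed_exponent)
    tracks_ed: dict[str, ScanTrack] = {}
    for chrom, length in chrom_lengths.items():
        sub = stats_ed[stats_ed.chrom == chrom]
        windows = make_windows(length, params.window_bp, params.step_bp)
        tracks_ed[chrom] = fit_track(
            sub.pos.to_numpy(), sub.ed_powered.to_numpy(), chrom, windows,
            "ed_powered", fit_method=params.fit_ed,
            window_size=params.window_bp, step=params.step_bp)
    masked_ed = {c: _mask_sparse(t, params.min_sites_per_window)
                 for c, t in tracks_ed.items()}
    all_fitted = np.concatenate([t.fitted for t in masked_ed.values()])
    thr_med = ed_threshold_median_sd(all_fitted, n_sd=params.ed_n_sd)
    thr_q = ed_threshold_quantile(all_fitted, q=params.ed_quantile)
    if params.ed_threshold_rule == "median_plus_3sd":
        ed_region_threshold = thr_med.scalar
    elif params.ed_threshold_rule == "quantile_99":
        ed_region_threshold = thr_q.scalar
    elif params.ed_threshold_rule == "refined":
        ed_region_threshold = max(thr_med.scalar, thr_q.scalar)
    else:
        raise ValueError(f"unknown ed_threshold_rule {params.ed_threshold_rule!r}")
    regions_ed: list[AssociationRegion] = []
    for chrom, track in masked_ed.items():
        regions_ed.extend(call_regions(track, ed_region_threshold, "ed"))
    result_ed = TrackResult(ledger=ledger_ed, tracks=tracks_ed,
                            thresholds={"median_plus_3sd": thr_med,
                                        "quantile_99": thr_q},
                            regions=regions_ed,
                            region_threshold=ed_region_threshold)

    intersection = intersect_tracks(regions_si, regions_ed)
    return ScanResult(snp_index=result_si, ed=result_ed,
                      intersection=intersection, params=params)


def _write_track_tsv(track: ScanTrack, path: Path) -> None:
    import pandas as pd
    pd.DataFrame({
        "chrom": track.chrom,
        "window_start": track.window_starts,
        "window_end": track.window_ends,
        "n_sites": track.n_sites,
        "fitted": track.fitted,
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_full_scan(config: PipelineConfig) -> ScanResult:
    """File-level pipeline: read VCF (and GFF), run both tracks, write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites = read_bulk_vcf(config.vcf, config.samples)
    if not sites:
        raise ValueError(f"no usable SNP records in {config.vcf}")
    genes: list[GeneInterval] | None = None
    if config.gff:
        genes = read_gene_intervals(config.gff)

    result = run_tracks(sites, params=config.scan,
                        chrom_lengths=config.chrom_lengths,
                        bulk_size=config.bulk_size, seed=config.seed)

    for name, tr in (("snp_index", result.snp_index), ("ed", result.ed)):
        (out / f"ledger_{name}.json").write_text(
            json.dumps(tr.ledger.to_dict(), indent=2) + "\n")
        for chrom, track in tr.tracks.items():
            _write_track_tsv(track, out / f"track_{name}_{chrom}.tsv")
        write_regions_tsv(tr.regions, out / f"regions_{name}.tsv", genes)
        write_regions_bed(tr.regions, out / f"regions_{name}.bed")
    write_regions_tsv(result.intersection, out / "regions_intersection.tsv", genes)
    write_regions_bed(result.intersection, out / "regions_intersection.bed")

    thresholds = {
        "delta_null_envelope": result.snp_index.thresholds["null_envelope"].values,
        "delta_region_threshold": result.snp_index.region_threshold,
        "ed_median_plus_3sd": result.ed.thresholds["median_plus_3sd"].scalar,
        "ed_quantile_99": result.ed.thresholds["quantile_99"].scalar,
        "ed_region_threshold": result.ed.region_threshold,
    }
    (out / "thresholds.json").write_text(
        json.dumps({str(k): v for k, v in thresholds.items()}, indent=2,
                   default=float) + "\n")
    manifest = {
        "bsascan_version": __version__,
        "seed": config.seed,
        "vcf": str(config.vcf),
        "gff": str(config.gff) if config.gff else None,
        "bulk_size": config.bulk_size,
        "scan": asdict(config.scan),
        "n_sites_read": len(sites),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
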