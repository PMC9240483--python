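"""Calling above-threshold regions, intersecting tracks, counting genes.

A region is a maximal run of consecutive above-threshold windows; it is
reported as the span from the first window's start to the LAST window's
start. With step-aligned windows this is the convention under which a
single-window excursion is a point (length 0.00 Mb) and region length is
``(end - start) / 1e6`` — the convention that reproduces published BSA-seq
interval lengths from their printed endpoints.

Runs separated by even one below-threshold (or empty) window are kept as
separate regions; no gap-bridging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import numpy as np

from .io import GeneInterval
from .scan import ScanTrack

__all__ = [
    "AssociationRegion", "call_regions", "region_length_mb",
    "intersect_tracks", "count_genes",
]


@dataclass(frozen=True)
class AssociationRegion:
    """A contiguous above-threshold genomic interval (1-based endpoints)."""

    chrom: str
    start_bp: int
    end_bp: int
    method: str  # snp_index | ed | intersection
    threshold_used: float
    peak_value: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"region start {self.start_bp} > end {self.end_bp}")

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.end_bp


def region_length_mb(region: AssociationRegion) -> float:
    """Region length in Mb: (end - start) / 1e6 (point regions are 0.00)."""
    return region.length_mb


def call_regions(track: ScanTrack, threshold: float, method: str
                 ) -> list[AssociationRegion]:
    """Maximal runs of consecutive windows with fitted >= threshold.

    Windows with no sites (NaN fit) break runs. Each region spans the first
    through the last window start of its run; a single-window run is a
    point region.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    above = np.zeros(track.fitted.size, dtype=bool)
    ok = np.isfinite(track.fitted)
    above[ok] = track.fitted[ok] >= threshold
    regions: list[AssociationRegion] = []
    idx = 0
    for flag, grp in groupby(above):
        run = len(list(grp))
        if flag:
            first, last = idx, idx + run - 1
            regions.append(AssociationRegion(
                chrom=track.chrom,
                start_bp=int(track.window_starts[first]),
                end_bp=int(track.window_starts[last]),
                method=method,
                threshold_used=float(threshold),
                peak_value=float(np.nanmax(track.fitted[first:last + 1])),
            ))
        idx += run
    return regions


def _check_sorted_disjoint(regions: Sequence[AssociationRegion], label: str) -> None:
    by_chrom: dict[str, list[AssociationRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        for prev, cur in zip(rs, rs[1:]):
            if cur.start_bp <= prev.end_bp:
                raise ValueError(
                    f"{label} regions unsorted/overlapping on {chrom}: "
                    f"[{prev.start_bp},{prev.end_bp}] then [{cur.start_bp},{cur.end_bp}]")


def intersect_tracks(regions_a: Sequence[AssociationRegion],
                     regions_b: Sequence[AssociationRegion]
                     ) -> list[AssociationRegion]:
    """Interval intersection of two per-track region lists (per chromosome)."""
    _check_sorted_disjoint(regions_a, "first input")
    _check_sorted_disjoint(regions_b, "second input")
    out: list[AssociationRegion] = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chrom != rb.chrom:
                continue
            lo = max(ra.start_bp, rb.start_bp)
            hi = min(ra.end_bp, rb.end_bp)
            if lo <= hi:
                out.append(AssociationRegion(
                    chrom=ra.chrom, start_bp=lo, end_bp=hi,
                    method="intersection",
                    threshold_used=max(ra.threshold_used, rb.threshold_used),
                    peak_value=min(ra.peak_value, rb.peak_value),
                ))
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def count_genes(region: AssociationRegion,
                gene_intervals: Sequence[GeneInterval]) -> int:
    """Number of genes overlapping the region by at least 1 bp (1-based)."""
    return sum(1 for g in gene_intervals
               if g.chrom == region.chrom
               and g.start <= region.end_bp and g.end >= region.start_bp)
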