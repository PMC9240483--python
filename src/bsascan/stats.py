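"""Per-site association statistics for bulked-segregant sequencing.

Two statistics contrast the allele composition of the phenotype-extreme
bulks at each SNP:

* SNP-index: within one bulk, the fraction of reads carrying the L-parent
  allele, ``SNPindex(aa) = Laa / (Laa + Saa)``; the association signal is
  the difference between bulks, ``dSNPindex = SNPindex(aa) - SNPindex(ab)``,
  which is ~0 under free segregation and approaches +/-1 at a fully selected
  locus.
* Euclidean distance (ED): the root of the summed squared differences of the
  four base frequencies (A, C, G, T) between bulks. ED needs no parent
  orientation and is 0 exactly when the two bulks have identical base
  composition. Raising ED to a power k (default 2, the "quadratic power")
  suppresses background noise relative to true peaks.

Zero-depth inputs raise: the filtering stage is contractually required to
remove sites where these ratios are undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import BASES, BulkSite

__all__ = [
    "SiteStatistics", "snp_index", "delta_snp_index", "base_frequencies",
    "euclidean_distance", "ed_power", "site_statistics", "statistics_frame",
]


@dataclass(frozen=True)
class SiteStatistics:
    """All per-site statistics at one SNP."""

    snp_index_aa: float
    snp_index_ab: float
    delta_snp_index: float
    ed: float
    ed_powered: float


def snp_index(l_depth: float, s_depth: float) -> float:
    """Fraction of a bulk's reads carrying the L allele: L / (L + S)."""
    total = l_depth + s_depth
    if total <= 0:
        raise ValueError("snp_index undefined at zero total depth")
    return l_depth / total


def delta_snp_index(idx_aa: float, idx_ab: float) -> float:
    """Difference of the two bulks' SNP-indices, in [-1, 1]."""
    for v in (idx_aa, idx_ab):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"SNP-index out of [0, 1]: {v}")
    return idx_aa - idx_ab


def base_frequencies(base_depths: Mapping[str, int]) -> dict[str, float]:
    """Per-base read frequencies (A, C, G, T) in one bulk; sums to 1."""
    total = sum(base_depths.get(b, 0) for b in BASES)
    if total <= 0:
        raise ValueError("base frequencies undefined at zero depth")
    return {b: base_depths.get(b, 0) / total for b in BASES}


def euclidean_distance(freqs_aa: Mapping[str, float],
                       freqs_ab: Mapping[str, float]) -> float:
    """Root of summed squared per-base frequency differences between bulks."""
    for f in (freqs_aa, freqs_ab):
        if abs(sum(f.get(b, 0.0) for b in BASES) - 1.0) > 1e-9:
            raise ValueError(f"frequency vector does not sum to 1: {dict(f)}")
    return math.sqrt(sum((freqs_aa.get(b, 0.0) - freqs_ab.get(b, 0.0)) ** 2
                         for b in BASES))


def ed_power(ed: float, k: float = 2.0) -> float:
    """ED raised to the noise-suppression exponent k (default quadratic)."""
    if ed < 0:
        raise ValueError(f"ed must be non-negative, got {ed}")
    if k < 1:
        raise ValueError(f"exponent must be >= 1, got {k}")
    return ed ** k


def site_statistics(site: BulkSite, k: float = 2.0) -> SiteStatistics:
    idx_aa = snp_index(site.Laa, site.Saa)
    idx_ab = snp_index(site.Lab, site.Sab)
    ed = euclidean_distance(base_frequencies(site.base_depths_aa),
                            base_frequencies(site.base_depths_ab))
    return SiteStatistics(
        snp_index_aa=idx_aa,
        snp_index_ab=idx_ab,
        delta_snp_index=delta_snp_index(idx_aa, idx_ab),
        ed=ed,
        ed_powered=ed_power(ed, k),
    )


def statistics_frame(sites: Iterable[BulkSite], k: float = 2.0) -> pd.DataFrame:
    """Per-site statistics table: chrom, pos, indices, delta, ED, ED^k."""
    rows = []
    for s in sites:
        st = site_statistics(s, k)
        rows.append((s.chrom, s.pos, st.snp_index_aa, st.snp_index_ab,
                     st.delta_snp_index, st.ed, st.ed_powered))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "snp_index_aa", "snp_index_ab",
        "delta_snp_index", "ed", "ed_powered"])
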