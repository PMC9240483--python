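"""Per-track SNP filtering with full accounting.

The two association statistics use different filtering ledgers:

* SNP-index track — removes, in order: multi-allelic records; sites whose
  two bulks carry identical L-allele read fractions at integer-depth
  resolution (the observed dSNPindex is exactly zero, so the site carries no
  between-bulk signal); sites with bulk read depth below four; sites not
  fixed for opposite alleles in the two parents (the index cannot be
  oriented). The identity test is exact integer cross-multiplication — a
  thresholded genotype-call rule would preferentially discard null sites and
  bias the retained set toward extreme dSNPindex values, wrecking the
  calibration of the windowed scan.
* ED track — removes, in order: sites with read depth below four in any
  bulk; sites with identical base composition in the two bulks (ED is
  exactly zero); multi-allelic records. Parents are not consulted: ED is
  defined on raw base frequencies.

Each site lands in exactly one bucket (first matching reason wins) or is
retained, so ``retained = total - sum(removed)`` holds by construction and
is re-validated on every ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

from .io import BASES, BulkSite

__all__ = [
    "PASS", "FilterLedger",
    "classify_snp_index_track", "classify_ed_track", "apply_filters",
    "SNP_INDEX_REASONS", "ED_REASONS",
]

PASS = "PASS"
Track = Literal["snp_index", "ed"]

SNP_INDEX_REASONS = ("multi_allelic", "identical_in_bulks", "low_depth",
                     "parent_uninformative")
ED_REASONS = ("low_depth", "identical_in_bulks", "multi_aligned")


@dataclass
class FilterLedger:
    """Accounting of one filtering run; invariant-checked on construction."""

    track: Track
    total_in: int
    removed_by_reason: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def __post_init__(self) -> None:
        if self.total_in < 0 or self.retained < 0:
            raise ValueError("counts must be non-negative")
        if any(c < 0 for c in self.removed_by_reason.values()):
            raise ValueError("removal counts must be non-negative")
        if self.retained != self.total_in - sum(self.removed_by_reason.values()):
            raise ValueError(
                f"ledger arithmetic violated: {self.total_in} - "
                f"{sum(self.removed_by_reason.values())} != {self.retained}")

    @classmethod
    def from_counts(cls, track: Track, total_in: int,
                    removed_by_reason: dict[str, int]) -> "FilterLedger":
        """Build a ledger from a total and removal counts; retained is derived."""
        retained = total_in - sum(removed_by_reason.values())
        return cls(track=track, total_in=total_in,
                   removed_by_reason=dict(removed_by_reason), retained=retained)

    def to_dict(self) -> dict:
        return {"track": self.track, "total_in": self.total_in,
                "removed_by_reason": dict(self.removed_by_reason),
                "retained": self.retained}


def classify_snp_index_track(site: BulkSite) -> str:
    """First matching removal reason for the SNP-index track, or PASS.

    'identical_in_bulks' holds when both bulks have reads and their L-allele
    read fractions are exactly equal (integer cross-multiplication:
    Laa*(Lab+Sab) == Lab*(Laa+Saa)); the observed dSNPindex is then exactly
    zero. Zero-depth bulks fall through to 'low_depth'.
    """
    if site.n_alt_alleles > 1:
        return "multi_allelic"
    d_aa = site.Laa + site.Saa
    d_ab = site.Lab + site.Sab
    if d_aa > 0 and d_ab > 0 and site.Laa * d_ab == site.Lab * d_aa:
        return "identical_in_bulks"
    if d_aa < 4 or d_ab < 4:
        return "low_depth"
    if not site.parent_informative:
        return "parent_uninformative"
    return PASS


def _base_freq_exact(site: BulkSite, which: str) -> tuple[Fraction, ...] | None:
    bd = site.base_depths_aa if which == "aa" else site.base_depths_ab
    total = sum(bd.get(b, 0) for b in BASES)
    if total == 0:
        return None
    return tuple(Fraction(bd.get(b, 0), total) for b in BASES)


def classify_ed_track(site: BulkSite) -> str:
    """First matching removal reason for the ED track, or PASS.

    'identical_in_bulks' means the base-frequency vectors agree exactly
    (integer cross-multiplication, no floating point), i.e. ED would be 0.
    """
    depth_aa = sum(site.base_depths_aa.get(b, 0) for b in BASES)
    depth_ab = sum(site.base_depths_ab.get(b, 0) for b in BASES)
    if depth_aa < 4 or depth_ab < 4:
        return "low_depth"
    fa = _base_freq_exact(site, "aa")
    fb = _base_freq_exact(site, "ab")
    if fa is not None and fa == fb:
        return "identical_in_bulks"
    if site.n_alt_alleles > 1:
        return "multi_aligned"
    return PASS


def apply_filters(sites: Sequence[BulkSite], track: Track
                  ) -> tuple[list[BulkSite], FilterLedger]:
    """Partition sites into retained + per-reason removal buckets."""
    if len(sites) == 0:
        raise ValueError("no input sites")
    if track == "snp_index":
        classify, reasons = classify_snp_index_track, SNP_INDEX_REASONS
    elif track == "ed":
        classify, reasons = classify_ed_track, ED_REASONS
    else:
        raise ValueError(f"unknown track {track!r}")

    removed = {r: 0 for r in reasons}
    retained: list[BulkSite] = []
    for site in sites:
        reason = classify(site)
        if reason == PASS:
            retained.append(site)
        else:
            removed[reason] += 1
    ledger = FilterLedger(track=track, total_in=len(sites),
                          removed_by_reason=removed, retained=len(retained))
    return retained, ledger
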