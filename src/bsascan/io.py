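"""Four-sample VCF and GFF3 input, plus tabular region output.

The experimental design served here is a bulked-segregant sequencing (BSA-seq)
cross: two inbred parents — labelled L (long-grain donor) and S (short-grain
donor) — and two phenotype-extreme F2 pools ("bulks"), each sequenced as a
single DNA mixture. Every VCF record is reduced to a :class:`BulkSite` that
carries parent-oriented allele read depths in both bulks (``Laa``/``Saa`` in
the L bulk, ``Lab``/``Sab`` in the S bulk) together with raw per-base A/C/G/T
read depths per bulk. Downstream statistics consume only these integers.

Coordinates are 1-based inclusive throughout (VCF/GFF convention); only BED
output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from cyvcf2 import VCF

BASES = ("A", "C", "G", "T")

ROLES = ("parent_L", "parent_S", "bulk_L", "bulk_S")


@dataclass
class BulkSite:
    """One biallelic-oriented variant site in the four-sample design.

    ``Laa``/``Saa`` are the L-bulk read depths supporting the L-parent and
    S-parent allele respectively; ``Lab``/``Sab`` the same for the S bulk.
    ``base_depths_aa``/``base_depths_ab`` give raw per-base depths (A, C, G,
    T) in the L and S bulk. When neither parent genotype pins the orientation
    (a parent heterozygous, missing, or both parents sharing an allele) the
    site keeps the ref-as-L convention and ``parent_informative`` is False;
    such sites are removed later by the filtering stage, never at read time.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    parent_L_depths: tuple[int, int]  # (ref reads, first-alt reads)
    parent_S_depths: tuple[int, int]
    Laa: int
    Saa: int
    Lab: int
    Sab: int
    base_depths_aa: dict[str, int] = field(default_factory=dict)
    base_depths_ab: dict[str, int] = field(default_factory=dict)
    parent_informative: bool = True
    missing_ad: bool = False

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def n_alt_alleles(self) -> int:
        return len(self.alts)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        depths = (*self.parent_L_depths, *self.parent_S_depths,
                  self.Laa, self.Saa, self.Lab, self.Sab)
        if any(d < 0 for d in depths):
            raise ValueError(f"negative read depth at {self.chrom}:{self.pos}")
        for bd in (self.base_depths_aa, self.base_depths_ab):
            for b in BASES:
                bd.setdefault(b, 0)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def _is_hom(gt: Sequence[int]) -> int | None:
    """Return the allele index if the genotype call is homozygous, else None."""
    alleles = [a for a in gt[:-1] if isinstance(a, int)]
    if len(alleles) != 2 or alleles[0] < 0 or alleles[0] != alleles[1]:
        return None
    return alleles[0]


def read_bulk_vcf(path: str | Path,
                  sample_order: Mapping[str, str] | None = None) -> list[BulkSite]:
    """Read a four-sample VCF into :class:`BulkSite` records.

    Parameters
    ----------
    path
        VCF (v4.x) with per-sample AD for all four samples.
    sample_order
        Mapping of roles (``parent_L``, ``parent_S``, ``bulk_L``, ``bulk_S``)
        to sample names in the file. Defaults to those literal names.

    Only SNP records (single-base REF and ALT alleles) are returned; the
    association formulas are defined on base frequencies, not indels.
    Orientation: the allele carried homozygously by parent_L is the L allele
    whenever the two parents are homozygous for different alleles; otherwise
    the site is flagged ``parent_informative=False`` and kept.
    """
    if sample_order is None:
        sample_order = {r: r for r in ROLES}
    missing_roles = [r for r in ROLES if r not in sample_order]
    if missing_roles:
        raise ValueError(f"sample_order lacks roles: {missing_roles}")

    vcf = VCF(str(path))
    idx: dict[str, int] = {}
    for role in ROLES:
        name = sample_order[role]
        if name not in vcf.samples:
            raise ValueError(f"sample {name!r} (role {role}) not in VCF samples {vcf.samples}")
        idx[role] = vcf.samples.index(name)

    sites: list[BulkSite] = []
    for v in vcf:
        alts = tuple(v.ALT)
        if len(v.REF) != 1 or v.REF not in BASES:
            continue
        if not alts or any(len(a) != 1 or a not in BASES for a in alts):
            continue
        alleles = (v.REF, *alts)

        ad = v.format("AD")
        missing_ad = False
        if ad is None:
            ad_rows = [[0] * len(alleles) for _ in range(len(vcf.samples))]
            missing_ad = True
        else:
            if ad.shape[1] != len(alleles):
                raise ValueError(
                    f"malformed AD at {v.CHROM}:{v.POS}: {ad.shape[1]} entries "
                    f"for {len(alleles)} alleles")
            ad_rows = ad.tolist()
            for row in ad_rows:
                for j, x in enumerate(row):
                    if x is None or x < 0:
                        row[j] = 0
                        missing_ad = True

        gts = v.genotypes
        hl = _is_hom(gts[idx["parent_L"]])
        hs = _is_hom(gts[idx["parent_S"]])
        informative = (hl is not None and hs is not None and hl != hs
                       and hl < len(alleles) and hs < len(alleles))
        if informative:
            l_allele, s_allele = hl, hs
        else:
            l_allele, s_allele = 0, 1  # ref-as-L fallback; flagged below

        ad_pl = ad_rows[idx["parent_L"]]
        ad_ps = ad_rows[idx["parent_S"]]
        ad_bl = ad_rows[idx["bulk_L"]]
        ad_bs = ad_rows[idx["bulk_S"]]

        def base_depths(row: list[int]) -> dict[str, int]:
            bd = {b: 0 for b in BASES}
            for allele, d in zip(alleles, row):
                bd[allele] += int(d)
            return bd

        sites.append(BulkSite(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=alts,
            parent_L_depths=(int(ad_pl[0]), int(ad_pl[1])),
            parent_S_depths=(int(ad_ps[0]), int(ad_ps[1])),
            Laa=int(ad_bl[l_allele]),
            Saa=int(ad_bl[s_allele]),
            Lab=int(ad_bs[l_allele]),
            Sab=int(ad_bs[s_allele]),
            base_depths_aa=base_depths(ad_bl),
            base_depths_ab=base_depths(ad_bs),
            parent_informative=informative,
            missing_ad=missing_ad,
        ))
    return sites


def read_gene_intervals(gff_path: str | Path) -> list[GeneInterval]:
    """Read gene features from a GFF3 file as 1-based inclusive intervals."""
    text = Path(gff_path).read_text()
    if not any(line and not line.startswith("#") for line in text.splitlines()):
        return []
    try:
        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils reports the offending line in its message
        raise ValueError(f"unparseable GFF3 {gff_path}: {exc}") from exc
    return [
        GeneInterval(chrom=f.seqid, start=f.start, end=f.end, gene_id=f.id)
        for f in db.features_of_type("gene")
    ]


def regions_frame(regions: Iterable, gene_intervals: Sequence[GeneInterval] | None = None
                  ) -> pd.DataFrame:
    """Region table with 1-based endpoints, length in Mb (2 decimals), gene count."""
    from .regions import count_genes  # local import: regions.py imports GeneInterval from here

    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "method": r.method,
            "threshold": r.threshold_used,
            "peak_value": r.peak_value,
            "length_mb": round(r.length_mb, 2),
        }
        if gene_intervals is not None:
            row["n_genes"] = count_genes(r, gene_intervals)
        rows.append(row)
    cols = ["chrom", "start_bp", "end_bp", "method", "threshold", "peak_value", "length_mb"]
    if gene_intervals is not None:
        cols.append("n_genes")
    return pd.DataFrame(rows, columns=cols)


def write_regions_tsv(regions: Iterable, path: str | Path,
                      gene_intervals: Sequence[GeneInterval] | None = None) -> None:
    regions_frame(regions, gene_intervals).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """BED output: 0-based half-open, name = method label."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.method}\n")
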