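"""Bulked-segregant F2 sequencing simulator with known ground truth.

Emulates the study design the scan statistics assume: an F2 population from a
cross of two inbred parents segregating for one large-effect additive QTL,
phenotype-extreme bulks (the longest- and shortest-grain individuals), and
pooled short-read sequencing of the two bulks plus both parents. The output
is the same :class:`~bsascan.io.BulkSite` records the VCF reader produces, a
VCFv4.2 file, and a :class:`TruthManifest` recording where the QTL really is
— so peak localisation and null calibration are testable without any
external data.

Model summary
-------------
* Meiosis: crossover count per chromosome ~ Poisson(map length in Morgans),
  crossover positions uniform on the genetic map, no interference (Haldane).
* Phenotype: ``mu + a*(g-1) + e`` with ``g`` the count of L alleles at the
  QTL marker and ``e ~ Normal(0, sigma_e^2)``; ``a`` and ``sigma_e`` are set
  from the configured proportion of variance explained (PVE), using additive
  variance ``a^2/2`` under F2 genotype frequencies 1:2:1.
* Reads: per site and pool, total depth ~ Poisson(mean depth); reads carrying
  the L allele ~ Binomial(depth, p*(1-err) + (1-p)*err) with ``p`` the pooled
  L-allele frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import BASES, BulkSite

__all__ = [
    "SimConfig", "F2Individual", "TruthManifest",
    "simulate_gamete", "simulate_f2", "select_bulks",
    "simulate_read_depths", "simulate_experiment", "write_simulated_vcf",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated bulked-segregant experiment.

    Defaults reproduce the study design the statistics were built for:
    1,307 F2 individuals, bulks of the 50 most extreme at each tail, ~70x
    pooled bulk coverage, ~35x parent coverage, and a QTL explaining 54.85%
    of the phenotypic variance. The genome is a desk-scale stand-in: twelve
    2.5 Mb chromosomes with a marker every 6 kb (~5,000 markers) at 4 cM/Mb
    and the QTL mid-chromosome-1, so the QTL-bearing chromosome is ~1/12 of
    the genome — the proportion a single rice chromosome occupies — and the
    other eleven provide genuine null background for threshold construction.
    """

    n_individuals: int = 1307
    bulk_size: int = 50
    n_chromosomes: int = 12
    chrom_length_bp: int = 2_500_000
    marker_spacing_bp: int = 6_000
    qtl_chrom: str = "chr1"
    qtl_pos_bp: int = 1_250_000
    pve: float = 0.5485
    mean_depth_bulk: float = 70.0
    mean_depth_parent: float = 35.0
    seq_error_rate: float = 0.001
    recomb_rate_cM_per_Mb: float = 4.0
    # phenotype scale (mm): mean +/- 3 SD spans the parental grain lengths
    phenotype_mean: float = 10.2
    phenotype_sd: float = 1.0
    # fraction of emitted sites where the parents are not informative
    # (both homozygous reference; the variant appears only in the bulks)
    noninformative_fraction: float = 0.10
    # fraction of informative sites emitted with a spurious third allele
    multiallelic_fraction: float = 0.005
    # fraction of sites in coverage-dropout territory (mean depth ~2 reads)
    low_depth_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pve < 1:
            raise ValueError(f"pve must be in [0, 1), got {self.pve}")
        if self.bulk_size > self.n_individuals // 2:
            raise ValueError("bulk_size must be <= n_individuals/2")
        if self.mean_depth_bulk <= 0 or self.mean_depth_parent <= 0:
            raise ValueError("mean depths must be positive")
        if not 1 <= int(self.qtl_chrom.removeprefix("chr") or 0) <= self.n_chromosomes:
            raise ValueError(f"qtl_chrom {self.qtl_chrom!r} outside chr1..chr{self.n_chromosomes}")
        if not 1 <= self.qtl_pos_bp <= self.chrom_length_bp:
            raise ValueError("qtl_pos_bp outside its chromosome")
        if self.marker_spacing_bp <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("lengths and spacings must be positive")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i}" for i in range(1, self.n_chromosomes + 1))

    def marker_positions(self) -> dict[str, np.ndarray]:
        """1-based marker positions per chromosome (regular grid)."""
        pos = np.arange(self.marker_spacing_bp, self.chrom_length_bp + 1,
                        self.marker_spacing_bp, dtype=np.int64)
        return {c: pos.copy() for c in self.chrom_names}

    def genetic_map_cM(self, positions_bp: np.ndarray) -> np.ndarray:
        return positions_bp / 1e6 * self.recomb_rate_cM_per_Mb


@dataclass
class F2Individual:
    """Two recombinant haplotypes per chromosome (1 = L allele) and a phenotype."""

    haplotypes: dict[str, np.ndarray]  # chrom -> (2, n_markers) uint8
    phenotype: float

    def genotype(self, chrom: str) -> np.ndarray:
        """Count of L alleles per marker, in {0, 1, 2}."""
        return self.haplotypes[chrom].sum(axis=0)


@dataclass
class TruthManifest:
    """Ground truth of one simulated experiment, for recovery tests."""

    qtl_chrom: str
    qtl_pos_bp: int  # position of the marker nearest the configured QTL
    pve: float
    seed: int
    l_pool: list[int] = field(default_factory=list)
    s_pool: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.l_pool) & set(self.s_pool):
            raise ValueError("bulk index sets overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def simulate_gamete(parent_haplotypes: np.ndarray, map_cM: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a pair of haplotypes on one chromosome.

    Crossover count ~ Poisson(map length in Morgans); crossover positions
    uniform on the genetic map; the starting haplotype is chosen with
    probability 1/2 and switches at every crossover (Haldane model, no
    interference).
    """
    map_cM = np.asarray(map_cM, dtype=float)
    if map_cM.size == 0:
        raise ValueError("empty marker list")
    if np.any(np.diff(map_cM) < 0):
        raise ValueError("genetic map positions must be non-decreasing")
    length_morgans = (map_cM[-1] - map_cM[0]) / 100.0
    start = int(rng.integers(2))
    n_xo = int(rng.poisson(length_morgans))
    if n_xo == 0:
        return parent_haplotypes[start].copy()
    xo = np.sort(rng.uniform(map_cM[0], map_cM[-1], size=n_xo))
    segment = np.searchsorted(xo, map_cM, side="left")
    hap_idx = (start + segment) % 2
    return parent_haplotypes[hap_idx, np.arange(map_cM.size)]


def select_bulks(phenotypes: Sequence[float], bulk_size: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``bulk_size`` largest (L pool) and smallest (S pool).

    Ties are broken by ascending individual index, deterministically; the L
    pool is filled first and the S pool drawn from the remainder, so the
    pools are disjoint even when ties span both tails.
    """
    pheno = np.asarray(phenotypes, dtype=float)
    n = pheno.size
    if bulk_size > n // 2:
        raise ValueError(f"bulk_size {bulk_size} > n/2 = {n // 2}")
    order_idx = np.arange(n)
    desc = np.lexsort((order_idx, -pheno))  # primary: phenotype desc, ties: index asc
    l_pool = np.sort(desc[:bulk_size])
    taken = np.zeros(n, dtype=bool)
    taken[l_pool] = True
    asc = np.lexsort((order_idx, pheno))
    s_pool = np.sort(asc[~taken[asc]][:bulk_size])
    return l_pool, s_pool


def simulate_f2(config: SimConfig, rng: np.random.Generator | None = None
                ) -> tuple[list[F2Individual], TruthManifest]:
    """Simulate the F2 population, phenotypes, and bulk membership.

    Each individual is two independent gametes from the (L x S) F1, whose
    own haplotypes are one all-L and one all-S chromosome set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = config.marker_positions()
    maps = {c: config.genetic_map_cM(p) for c, p in positions.items()}
    f1 = {c: np.vstack([np.ones(p.size, dtype=np.uint8),
                        np.zeros(p.size, dtype=np.uint8)])
          for c, p in positions.items()}

    qtl_positions = positions[config.qtl_chrom]
    qtl_marker = int(np.argmin(np.abs(qtl_positions - config.qtl_pos_bp)))

    sigma_p = config.phenotype_sd
    a = np.sqrt(2.0 * config.pve) * sigma_p
    sigma_e = np.sqrt(1.0 - config.pve) * sigma_p

    individuals: list[F2Individual] = []
    for _ in range(config.n_individuals):
        haps = {c: np.vstack([simulate_gamete(f1[c], maps[c], rng),
                              simulate_gamete(f1[c], maps[c], rng)])
                for c in config.chrom_names}
        g = int(haps[config.qtl_chrom][:, qtl_marker].sum())
        pheno = config.phenotype_mean + a * (g - 1) + rng.normal(0.0, sigma_e)
        individuals.append(F2Individual(haplotypes=haps, phenotype=float(pheno)))

    l_pool, s_pool = select_bulks([i.phenotype for i in individuals], config.bulk_size)
    manifest = TruthManifest(
        qtl_chrom=config.qtl_chrom,
        qtl_pos_bp=int(qtl_positions[qtl_marker]),
        pve=config.pve,
        seed=config.seed,
        l_pool=[int(i) for i in l_pool],
        s_pool=[int(i) for i in s_pool],
    )
    return individuals, manifest


def simulate_read_depths(l_allele_count: int, pool_size: int, mean_depth: float,
                         error_rate: float, rng: np.random.Generator
                         ) -> tuple[int, int]:
    """Pooled read depths (L reads, S reads) at one site for one pool.

    ``p = l_allele_count / (2 * pool_size)`` is the pooled L-allele
    frequency; total depth ~ Poisson(mean_depth); L reads ~ Binomial with a
    symmetric per-read error toward the other allele.
    """
    if pool_size <= 0:
        raise ValueError("empty pool")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    p = l_allele_count / (2 * pool_size)
    d = int(rng.poisson(mean_depth))
    p_read = p * (1 - error_rate) + (1 - p) * error_rate
    l_reads = int(rng.binomial(d, p_read)) if d > 0 else 0
    return l_reads, d - l_reads


def _pool_depth_arrays(pool_freq: np.ndarray, mean_depth, error_rate: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised variant of :func:`simulate_read_depths`; mean_depth may be per-site."""
    d = rng.poisson(mean_depth, size=pool_freq.size)
    p_read = pool_freq * (1 - error_rate) + (1 - pool_freq) * error_rate
    l_reads = rng.binomial(d, p_read)
    return l_reads, d - l_reads


def simulate_experiment(config: SimConfig
                        ) -> tuple[list[BulkSite], TruthManifest]:
    """Full experiment: F2 cross -> bulks -> pooled read depths -> BulkSites.

    Three independent RNG streams (cross, site layout, read sampling) are
    spawned from the configured seed, so e.g. changing the read model does
    not perturb the cross. A configurable fraction of sites is emitted as
    parent-uninformative (variant absent from both parents) and a small
    fraction with a spurious third allele, so the filtering stage has
    realistic material to remove.
    """
    ss = np.random.SeedSequence(config.seed)
    f2_rng, site_rng, depth_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    individuals, manifest = simulate_f2(config, rng=f2_rng)
    positions = config.marker_positions()

    sites: list[BulkSite] = []
    err = config.seq_error_rate
    for chrom in config.chrom_names:
        pos = positions[chrom]
        k = pos.size
        geno = np.stack([ind.genotype(chrom) for ind in individuals])  # (n, k)
        l_counts_aa = geno[manifest.l_pool].sum(axis=0)
        l_counts_ab = geno[manifest.s_pool].sum(axis=0)
        p_aa = l_counts_aa / (2 * config.bulk_size)
        p_ab = l_counts_ab / (2 * config.bulk_size)

        noninf = site_rng.random(k) < config.noninformative_fraction
        multi = (~noninf) & (site_rng.random(k) < config.multiallelic_fraction)
        # spurious bulk-only variants share one allele frequency in both bulks
        spur_freq = site_rng.uniform(0.05, 0.5, size=k)
        p_aa = np.where(noninf, spur_freq, p_aa)
        p_ab = np.where(noninf, spur_freq, p_ab)

        ref_idx = site_rng.integers(0, 4, size=k)
        alt_off = site_rng.integers(1, 4, size=k)
        alt_idx = (ref_idx + alt_off) % 4
        third_idx = np.array([
            next(b for b in range(4) if b != r and b != a)
            for r, a in zip(ref_idx, alt_idx)
        ])
        # at parent-uninformative sites the reader falls back to ref-as-L;
        # emit them that way so the VCF round trip is exact
        l_is_ref = (site_rng.random(k) < 0.5) | noninf

        # coverage-dropout sites: bulk depth collapses to ~2 reads
        low_depth = site_rng.random(k) < config.low_depth_fraction
        bulk_depth = np.where(low_depth, 2.0, config.mean_depth_bulk)
        laa, saa = _pool_depth_arrays(p_aa, bulk_depth, err, depth_rng)
        lab, sab = _pool_depth_arrays(p_ab, bulk_depth, err, depth_rng)
        # parents are homozygous; sequencing errors land on the other allele
        d_pl = depth_rng.poisson(config.mean_depth_parent, size=k)
        e_pl = depth_rng.binomial(d_pl, err)
        d_ps = depth_rng.poisson(config.mean_depth_parent, size=k)
        e_ps = depth_rng.binomial(d_ps, err)
        # third-allele reads at spurious multi-allelic sites
        d3_aa = np.where(multi, depth_rng.binomial(4, 0.5, size=k), 0)
        d3_ab = np.where(multi, depth_rng.binomial(4, 0.5, size=k), 0)

        base_names = np.array(BASES)
        for i in range(k):
            ref_b = base_names[ref_idx[i]]
            alt_b = base_names[alt_idx[i]]
            l_base, s_base = (ref_b, alt_b) if l_is_ref[i] else (alt_b, ref_b)
            alts = (alt_b,)
            if multi[i] and (d3_aa[i] > 0 or d3_ab[i] > 0):
                alts = (alt_b, base_names[third_idx[i]])
            bd_aa = {l_base: int(laa[i]), s_base: int(saa[i])}
            bd_ab = {l_base: int(lab[i]), s_base: int(sab[i])}
            if len(alts) > 1:
                bd_aa[alts[1]] = int(d3_aa[i])
                bd_ab[alts[1]] = int(d3_ab[i])
            main_pl, err_pl = int(d_pl[i] - e_pl[i]), int(e_pl[i])
            main_ps, err_ps = int(d_ps[i] - e_ps[i]), int(e_ps[i])
            if noninf[i]:
                # both parents homozygous reference; variant only in the bulks
                pl = (main_pl, err_pl)
                ps = (main_ps, err_ps)
            elif l_is_ref[i]:
                pl = (main_pl, err_pl)
                ps = (err_ps, main_ps)
            else:
                pl = (err_pl, main_pl)
                ps = (main_ps, err_ps)
            sites.append(BulkSite(
                chrom=chrom, pos=int(pos[i]), ref=str(ref_b), alts=alts,
                parent_L_depths=pl, parent_S_depths=ps,
                Laa=int(laa[i]), Saa=int(saa[i]),
                Lab=int(lab[i]), Sab=int(sab[i]),
                base_depths_aa=bd_aa, base_depths_ab=bd_ab,
                parent_informative=not bool(noninf[i]),
            ))
    return sites, manifest


def _vcf_gt(ref_reads: int, alt_reads: int) -> str:
    if ref_reads == 0 and alt_reads == 0:
        return "./."
    tot = ref_reads + alt_reads
    frac = alt_reads / tot
    if frac >= 0.75:
        return "1/1"
    if frac <= 0.25:
        return "0/0"
    return "0/1"


def write_simulated_vcf(sites: Sequence[BulkSite], path: str | Path,
                        contig_lengths: dict[str, int] | None = None) -> None:
    """Write sites as a VCFv4.2 file with samples parent_L, parent_S, bulk_L, bulk_S.

    FORMAT is GT:AD:DP. Parents are emitted with their (homozygous) truth
    genotypes; bulk genotypes are called from read fractions and carry no
    information downstream (the reader uses AD). Sites must be sorted by
    (chromosome, position).
    """
    chrom_order: list[str] = []
    last_pos: dict[str, int] = {}
    for s in sites:
        if s.chrom not in last_pos:
            if chrom_order and s.chrom in chrom_order:
                raise ValueError("sites not sorted: chromosome blocks interleaved")
            chrom_order.append(s.chrom)
            last_pos[s.chrom] = 0
        if s.chrom != chrom_order[-1] or s.pos < last_pos[s.chrom]:
            raise ValueError(f"sites not sorted at {s.chrom}:{s.pos}")
        last_pos[s.chrom] = s.pos

    if contig_lengths is None:
        contig_lengths = {c: last_pos[c] for c in chrom_order}

    lines = [
        "##fileformat=VCFv4.2",
        "##source=bsascan-simulate",
    ]
    for c in contig_lengths:
        lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        "parent_L\tparent_S\tbulk_L\tbulk_S",
    ]

    for s in sites:
        alleles = (s.ref, *s.alts)
        l_allele = s.ref if s.parent_L_depths[0] >= s.parent_L_depths[1] else s.alts[0]
        if not s.parent_informative:
            l_allele = s.ref
        s_allele = s.alts[0] if l_allele == s.ref else s.ref

        def bulk_ad(l_reads: int, s_reads: int, bd: dict[str, int]) -> list[int]:
            ad = []
            for a in alleles:
                if a == l_allele:
                    ad.append(l_reads)
                elif a == s_allele:
                    ad.append(s_reads)
                else:
                    ad.append(bd.get(a, 0))
            return ad

        ad_bl = bulk_ad(s.Laa, s.Saa, s.base_depths_aa)
        ad_bs = bulk_ad(s.Lab, s.Sab, s.base_depths_ab)
        ad_pl = [s.parent_L_depths[0], s.parent_L_depths[1]] + [0] * (len(alleles) - 2)
        ad_ps = [s.parent_S_depths[0], s.parent_S_depths[1]] + [0] * (len(alleles) - 2)

        if s.parent_informative:
            gt_pl = "0/0" if l_allele == s.ref else "1/1"
            gt_ps = "1/1" if l_allele == s.ref else "0/0"
        else:
            gt_pl = gt_ps = "0/0"

        def fmt(gt: str, ad: list[int]) -> str:
            return f"{gt}:{','.join(str(x) for x in ad)}:{sum(ad)}"

        gt_bl = _vcf_gt(ad_bl[0], sum(ad_bl[1:]))
        gt_bs = _vcf_gt(ad_bs[0], sum(ad_bs[1:]))

        lines.append("\t".join([
            s.chrom, str(s.pos), ".", s.ref, ",".join(s.alts), ".", "PASS", ".",
            "GT:AD:DP",
            fmt(gt_pl, ad_pl), fmt(gt_ps, ad_ps), fmt(gt_bl, ad_bl), fmt(gt_bs, ad_bs),
        ]))

    Path(path).write_text("\n".join(lines) + "\n")
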