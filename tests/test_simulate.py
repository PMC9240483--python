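"""F2 cross, bulk selection, read sampling, and VCF emission."""

import numpy as np
import pytest

from bsascan import (SimConfig, read_bulk_vcf, select_bulks, simulate_f2,
                     write_simulated_vcf)
from bsascan.simulate import simulate_experiment, simulate_gamete, simulate_read_depths


def _two_marker_recombinant_fraction(distance_cM, n, rng):
    haps = np.array([[1, 1], [0, 0]], dtype=np.uint8)
    m = np.array([0.0, distance_cM])
    rec = sum(g[0] != g[1] for g in (simulate_gamete(haps, m, rng) for _ in range(n)))
    return rec / n


class TestGamete:
    def test_zero_map_length_copies_a_parental_haplotype(self, rng):
        haps = np.array([[1], [0]], dtype=np.uint8)
        drawn = {int(simulate_gamete(haps, np.array([0.0]), rng)[0])
                 for _ in range(200)}
        assert drawn == {0, 1}  # both parents appear; no third state

    @pytest.mark.parametrize("distance_cM", [10.0, 50.0, 100.0])
    def test_recombinant_fraction_matches_haldane(self, distance_cM, rng):
        # Haldane map function: r = (1 - exp(-2d)) / 2 with d in Morgans
        expected = (1 - np.exp(-2 * distance_cM / 100)) / 2
        observed = _two_marker_recombinant_fraction(distance_cM, 10_000, rng)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_tight_linkage_rarely_recombines(self, rng):
        assert _two_marker_recombinant_fraction(0.001, 10_000, rng) < 0.005

    def test_empty_marker_list_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            simulate_gamete(np.empty((2, 0), dtype=np.uint8), np.array([]), rng)


class TestF2:
    small = dict(n_individuals=2000, bulk_size=50, n_chromosomes=1,
                 chrom_length_bp=1_000_000, marker_spacing_bp=200_000,
                 qtl_chrom="chr1", qtl_pos_bp=500_000)

    def test_genotype_frequencies_are_1_2_1(self):
        from scipy.stats import chisquare
        cfg = SimConfig(n_individuals=10_000, **{k: v for k, v in self.small.items()
                                                 if k != "n_individuals"}, seed=5)
        inds, _ = simulate_f2(cfg)
        geno = np.stack([i.genotype("chr1") for i in inds])
        for m in range(geno.shape[1]):
            counts = np.bincount(geno[:, m], minlength=3)
            freqs = counts / counts.sum()
            assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)
        stat, p = chisquare(np.bincount(geno[:, 0], minlength=3),
                            [2500, 5000, 2500])
        assert p > 0.001

    def test_qtl_explains_configured_variance_fraction(self):
        cfg = SimConfig(pve=0.5485, seed=11, **self.small)
        inds, man = simulate_f2(cfg)
        qtl_idx = np.argmin(np.abs(cfg.marker_positions()["chr1"] - man.qtl_pos_bp))
        g = np.array([i.genotype("chr1")[qtl_idx] for i in inds])
        y = np.array([i.phenotype for i in inds])
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert r2 == pytest.approx(0.5485, abs=0.05)

    def test_null_qtl_uncorrelated_with_phenotype(self):
        cfg = SimConfig(pve=0.0, seed=12, **self.small)
        inds, man = simulate_f2(cfg)
        qtl_idx = np.argmin(np.abs(cfg.marker_positions()["chr1"] - man.qtl_pos_bp))
        g = np.array([i.genotype("chr1")[qtl_idx] for i in inds])
        y = np.array([i.phenotype for i in inds])
        assert abs(np.corrcoef(g, y)[0, 1]) < 0.08

    def test_pve_of_one_rejected(self):
        with pytest.raises(ValueError, match="pve"):
            SimConfig(pve=1.0)

    def test_bulk_membership_is_phenotype_extremes(self):
        cfg = SimConfig(seed=3, **self.small)
        inds, man = simulate_f2(cfg)
        y = np.array([i.phenotype for i in inds])
        assert y[man.l_pool].min() > y[man.s_pool].max()


class TestSelectBulks:
    def test_strictly_ordered_input(self):
        l_pool, s_pool = select_bulks(np.arange(1, 201, dtype=float), 50)
        assert list(l_pool) == list(range(150, 200))
        assert list(s_pool) == list(range(0, 50))

    def test_all_ties_resolved_by_index_and_disjoint(self):
        l_pool, s_pool = select_bulks(np.zeros(10), 2)
        assert list(l_pool) == [0, 1]
        assert set(l_pool).isdisjoint(s_pool)

    def test_oversized_bulk_rejected(self):
        with pytest.raises(ValueError, match="bulk_size"):
            select_bulks(np.arange(10.0), 6)


class TestReadDepths:
    def test_fixed_pool_with_no_error_gives_no_s_reads(self, rng):
        for _ in range(50):
            _, s = simulate_read_depths(100, 50, 70, 0.0, rng)
            assert s == 0

    def test_half_frequency_pool_mean_read_fraction(self, rng):
        fracs = []
        for _ in range(10_000):
            l, s = simulate_read_depths(50, 50, 70, 0.001, rng)
            if l + s:
                fracs.append(l / (l + s))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_error_rate_sets_residual_fraction(self, rng):
        fracs = [simulate_read_depths(0, 50, 1000, 0.001, rng)[0] / 1000
                 for _ in range(1000)]
        assert np.mean(fracs) == pytest.approx(0.001, abs=0.0005)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="pool"):
            simulate_read_depths(0, 0, 70, 0.0, rng)


class TestVcfOutput:
    tiny = dict(n_individuals=100, bulk_size=20, n_chromosomes=2,
                chrom_length_bp=500_000, marker_spacing_bp=50_000,
                qtl_chrom="chr1", qtl_pos_bp=250_000)

    def test_round_trip_preserves_every_depth(self, tmp_path):
        cfg = SimConfig(seed=42, **self.tiny)
        sites, _ = simulate_experiment(cfg)
        path = tmp_path / "sim.vcf"
        write_simulated_vcf(sites, path)
        back = read_bulk_vcf(path)
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert (a.Laa, a.Saa, a.Lab, a.Sab) == (b.Laa, b.Saa, b.Lab, b.Sab)
            assert a.parent_L_depths == b.parent_L_depths
            assert a.parent_S_depths == b.parent_S_depths
            assert a.parent_informative == b.parent_informative
            assert a.base_depths_aa == b.base_depths_aa

    def test_identical_seed_gives_byte_identical_vcf(self, tmp_path):
        for name in ("a.vcf", "b.vcf"):
            sites, _ = simulate_experiment(SimConfig(seed=7, **self.tiny))
            write_simulated_vcf(sites, tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_handcrafted_depths_survive_round_trip(self, tmp_path, site_factory):
        site = site_factory(pl=(30, 0), ps=(0, 28), laa=41, saa=29, lab=12, sab=60)
        path = tmp_path / "one.vcf"
        write_simulated_vcf([site], path)
        (back,) = read_bulk_vcf(path)
        assert (back.parent_L_depths, back.parent_S_depths) == ((30, 0), (0, 28))
        assert (back.Laa, back.Saa, back.Lab, back.Sab) == (41, 29, 12, 60)

    def test_empty_site_list_yields_parseable_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_simulated_vcf([], path, contig_lengths={"chr1": 1000})
        assert read_bulk_vcf(path) == []

    def test_unsorted_sites_rejected(self, tmp_path, site_factory):
        sites = [site_factory(pos=2000), site_factory(pos=1000)]
        with pytest.raises(ValueError, match="sorted"):
            write_simulated_vcf(sites, tmp_path / "bad.vcf")
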