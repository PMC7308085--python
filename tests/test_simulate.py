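"""Generator: layout invariants, determinism, and distribution recovery."""

from __future__ import annotations

import numpy as np
import pytest

import nucmap as nm
from nucmap.simulate import Nucleosome, SizingError

from oracles import mc_wrapped_fraction


class TestBuildGenomeModel:
    def test_empty_gene_list_gives_bare_genome(self):
        model = nm.build_genome_model(nm.SimConfig(n_genes=0))
        assert model.genes == [] and model.nucleosomes == []
        assert sum(model.chrom_sizes.values()) > 0

    def test_identical_config_is_byte_identical(self):
        a = nm.build_genome_model(nm.SimConfig(seed=1, n_genes=60))
        b = nm.build_genome_model(nm.SimConfig(seed=1, n_genes=60))
        assert a.nucleosome_table().equals(b.nucleosome_table())
        assert a.gene_table().equals(b.gene_table())
        assert a.promoter_truth == b.promoter_truth

    def test_wide_class_width_mean_matches_distribution(self):
        cfg = nm.SimConfig(n_genes=200, wide_fraction=0.3, seed=7)
        model = nm.build_genome_model(cfg)
        widths = [e - s for (s, e, k) in model.promoter_truth.values()
                  if k == "wide"]
        # divergent partners share an NDR; count each planted NDR once
        widths = np.array(sorted(set(
            (s, e) for (s, e, k) in model.promoter_truth.values()
            if k == "wide"
        )))
        widths = widths[:, 1] - widths[:, 0]
        se = cfg.wide_width_sd / np.sqrt(len(widths))
        assert abs(widths.mean() - cfg.wide_width_mean) < 3 * se

    def test_layout_invariants(self, chip_sim):
        model = chip_sim["model"]
        model.validate()  # dyad bounds, 147 bp spacing, TSS-NDR adjacency
        # planted NDR widths inside the configured extraction bounds
        for s, e, _ in model.promoter_truth.values():
            assert 75 <= e - s <= 600
        # tDNAs have flanking nucleosomes but nothing mid-feature
        tdna_tss = {g.tss: g.chrom for g in model.genes if g.biotype == "tDNA"}
        for tss, chrom in tdna_tss.items():
            for n in model.nucleosomes:
                if n.chrom == chrom:
                    assert not (tss - 40 <= n.dyad <= tss + 40)

    def test_interposed_only_at_wide_promoters(self, chip_sim):
        model = chip_sim["model"]
        wide_ids = {g for g, (_, _, k) in model.promoter_truth.items()
                    if k == "wide"}
        interposed = [n for n in model.nucleosomes if n.role == "interposed"]
        assert interposed
        for n in interposed:
            assert n.gene_id in wide_ids
            assert 0.2 <= n.occupancy <= 0.4

    def test_hmo1_affinity_zero_at_tdnas_scales_with_width(self, chip_sim):
        model = chip_sim["model"]
        w = model.affinities["hmo1"]
        for i, n in enumerate(model.nucleosomes):
            if n.role == "tdna_flank":
                assert w[i] == 0.0
            elif n.role in ("wide_flank", "narrow_flank"):
                assert w[i] == pytest.approx(n.ndr_width / 150.0)

    def test_too_small_genome_raises(self):
        with pytest.raises(SizingError):
            nm.build_genome_model(
                nm.SimConfig(n_genes=50, n_chroms=1, chrom_len=5_000)
            )


class TestSimulateAlignments:
    def test_degenerate_noise_pins_five_prime(self):
        cfg = nm.SimConfig(seed=0, fragment_len_sd=1e-9)
        model = nm.GenomeModel(
            {"chrZ": 10_000}, [],
            [Nucleosome("chrZ", 5_000, 1.0, 0.0, "body")],
            {}, [], {}, cfg,
        )
        recs = nm.simulate_alignments(model, 500, "input", seed=4)
        assert len(recs) == 500
        for r in recs:
            assert r.length == 147
            assert (r.pos5 == 4_927) if r.strand == "+" else (r.pos5 == 5_073)

    def test_affinity_weights_set_sampling_shares(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 20_000, "fac", seed=2)
        share_a = np.mean([r.pos5 < 7_500 for r in recs])
        se = np.sqrt(0.8 * 0.2 / 20_000)
        assert abs(share_a - 0.8) < 3 * se

    def test_input_ignores_affinities(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 20_000, "input", seed=2)
        share_a = np.mean([r.pos5 < 7_500 for r in recs])
        assert abs(share_a - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_midpoint_sd_recovers_fuzz(self):
        cfg = nm.SimConfig(seed=0, fuzz_sd=12.0)
        model = nm.GenomeModel(
            {"chrZ": 40_000}, [],
            [Nucleosome("chrZ", 20_000, 1.0, cfg.fuzz_sd, "body")],
            {}, [], {}, cfg,
        )
        recs = nm.simulate_alignments(model, 100_000, "input", seed=9)
        mids = np.array([(r.start + r.end - 1) / 2 for r in recs])
        # rounding of offsets and odd/even lengths adds ~1/3 bp^2 variance
        assert abs(mids.std() - 12.0) < 0.5

    def test_fragment_length_distribution(self, chip_sim):
        lengths = np.array([r.length for r in chip_sim["records"]])
        se = 5.0 / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 147.0) < 3 * se + 0.05
        assert lengths.min() >= 100 and lengths.max() <= 200

    def test_unknown_factor_rejected(self, two_nuc_model):
        with pytest.raises(KeyError):
            nm.simulate_alignments(two_nuc_model, 10, "nosuch", seed=0)

    def test_determinism(self, two_nuc_model):
        a = nm.simulate_alignments(two_nuc_model, 100, "input", seed=5)
        b = nm.simulate_alignments(two_nuc_model, 100, "input", seed=5)
        assert a == b


class TestInjectDuplicates:
    def test_duplicate_count_formula(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 600, "input", seed=1)
        out = nm.inject_duplicates(recs, 0.4, seed=2)
        assert len(out) == 1_000
        assert out[:600] == recs  # originals untouched, in order

    def test_sixty_five_percent_on_350(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 350, "input", seed=1)
        out = nm.inject_duplicates(recs, 0.65, seed=2)
        assert len(out) == 1_000

    def test_target_zero_is_identity(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 50, "input", seed=1)
        assert nm.inject_duplicates(recs, 0.0, seed=2) == recs

    def test_copies_are_exact_coordinate_clones(self, two_nuc_model):
        recs = nm.simulate_alignments(two_nuc_model, 100, "input", seed=1)
        out = nm.inject_duplicates(recs, 0.5, seed=3)
        originals = {r.name: r for r in recs}
        for copy in out[100:]:
            src = originals[copy.name.rsplit(":dup", 1)[0]]
            assert (copy.chrom, copy.pos5, copy.strand, copy.length) == (
                src.chrom, src.pos5, src.strand, src.length)

    def test_empty_input_with_target_raises(self):
        with pytest.raises(ValueError):
            nm.inject_duplicates([], 0.4, seed=0)


class TestProtectionSim:
    def test_fully_wrapped_geometry(self):
        pcfg = nm.ProtectionSimConfig(
            p_wrap_left=1.0, p_wrap_right=1.0, jitter_sd=0.0,
            n_molecules=200, seed=3,
        )
        reads, truth = nm.simulate_protection_reads(pcfg)
        assert (truth["start"] == 11).all()
        assert (truth["end"] == 158).all()
        assert (truth["length"] == 147).all()
        for r in reads:
            assert len(r.sequence) == 8 + 147

    def test_no_pcr_means_each_umi_once(self):
        pcfg = nm.ProtectionSimConfig(pcr_mean_copies=0.0, n_molecules=300,
                                      seed=4)
        reads, truth = nm.simulate_protection_reads(pcfg)
        assert len(reads) == 300
        assert (truth["n_copies"] == 1).all()

    def test_truth_wrapped_fraction_matches_mc_oracle(self):
        pcfg = nm.ProtectionSimConfig(
            p_wrap_left=0.7, p_wrap_right=0.7,
            unwrap_mean_left=15.0, unwrap_mean_right=15.0,
            n_molecules=20_000, seed=11,
        )
        _, truth = nm.simulate_protection_reads(pcfg)
        est = (truth["length"] >= 135).mean()
        oracle = mc_wrapped_fraction(pcfg, 1_000_000, seed=99)
        assert abs(est - oracle) < 0.02

    def test_determinism(self):
        pcfg = nm.ProtectionSimConfig(n_molecules=100, seed=6)
        r1, t1 = nm.simulate_protection_reads(pcfg)
        r2, t2 = nm.simulate_protection_reads(pcfg)
        assert r1 == r2 and t1.equals(t2)
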