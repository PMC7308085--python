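"""NDR extraction, anchoring, classes, and occupancy aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nucmap as nm
from nucmap.ndr import AnchoredFeature
from nucmap.nucleosomes import NucleosomeCall


def call(dyad, chrom="chr1"):
    return NucleosomeCall(chrom, dyad, 10.0, 5.0)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "tss", "strand",
                                       "biotype"])


class TestInternucleosomalIntervals:
    def test_interval_arithmetic(self):
        out = nm.internucleosomal_intervals([call(1_000), call(1_400)])
        assert out == [("chr1", 1_074, 1_327)]
        assert out[0][2] - out[0][1] == 253  # d2 - d1 - 147

    def test_abutting_footprints_discarded(self):
        assert nm.internucleosomal_intervals([call(1_000), call(1_147)]) == []

    def test_single_call_no_intervals(self):
        assert nm.internucleosomal_intervals([call(1_000)]) == []

    def test_chromosome_boundaries_not_bridged(self):
        calls = [call(1_000, "chr1"), call(1_000, "chr2")]
        assert nm.internucleosomal_intervals(calls) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            nm.internucleosomal_intervals([call(1_400), call(1_000)])


class TestExtractNdrs:
    GENES = genes_df([("gA", "chr1", 2_280, "+", "protein_coding")])

    def test_short_interval_rejected(self):
        out = nm.extract_ndrs([("chr1", 2_250, 2_300)], self.GENES)
        assert out == []  # 50 bp < 75 bp bound, TSS inside notwithstanding

    def test_anchor_is_nearest_edge(self):
        out = nm.extract_ndrs([("chr1", 2_000, 2_300)], self.GENES)
        assert len(out) == 1
        r = out[0]
        assert (r.anchor, r.anchor_side) == (2_300, "right")
        assert r.orientation == "+"

    def test_adjacent_tss_within_73bp_qualifies(self):
        genes = genes_df([("gA", "chr1", 2_360, "+", "protein_coding")])
        assert len(nm.extract_ndrs([("chr1", 2_000, 2_300)], genes)) == 1
        genes_far = genes_df([("gA", "chr1", 2_374, "+", "protein_coding")])
        assert nm.extract_ndrs([("chr1", 2_000, 2_300)], genes_far) == []

    def test_divergent_pair_represented_once(self):
        genes = genes_df([
            ("gL", "chr1", 2_020, "-", "protein_coding"),
            ("gR", "chr1", 2_280, "+", "protein_coding"),
        ])
        out = nm.extract_ndrs([("chr1", 2_000, 2_300)], genes)
        assert len(out) == 1
        assert sorted(out[0].tss_ids) == ["gL", "gR"]

    def test_non_coding_tss_ignored(self):
        genes = genes_df([("tA", "chr1", 2_100, "+", "tDNA")])
        assert nm.extract_ndrs([("chr1", 2_000, 2_300)], genes) == []

    def test_recovery_of_planted_promoters(self, chip_sim):
        """>=95% of planted NDRs recovered with width error <= 30 bp;
        divergent-pair record count equals the planted pair count."""
        model = chip_sim["model"]
        ndrs = nm.extract_ndrs(
            nm.internucleosomal_intervals(chip_sim["calls"]),
            model.gene_table(),
        )
        for r in ndrs:  # emitted records satisfy their own contract
            assert 75 <= r.length <= 600
        by_gene = {}
        for r in ndrs:
            for g in r.tss_ids:
                by_gene[g] = r
        n_ok = 0
        for gid, (s, e, _) in model.promoter_truth.items():
            r = by_gene.get(gid)
            if r is not None and abs(r.length - (e - s)) <= 30:
                n_ok += 1
        assert n_ok / len(model.promoter_truth) >= 0.95
        n_div_records = sum(1 for r in ndrs if len(r.tss_ids) == 2)
        assert n_div_records == len(model.divergent_pairs)

    def test_tertiles_agree_with_planted_classes(self, chip_sim):
        """Tertile extremes recover the planted narrow/wide split."""
        model = chip_sim["model"]
        ndrs = nm.anchor_sort(
            nm.extract_ndrs(
                nm.internucleosomal_intervals(chip_sim["calls"]),
                model.gene_table(),
            )
        )
        nm.length_classes(ndrs, k=3)
        truth_class = {g: k for g, (_, _, k) in model.promoter_truth.items()}
        n_ok = n_tot = 0
        for r in ndrs:
            if r.length_class == 2:
                continue  # middle tertile is ambiguous by construction
            want = "wide" if r.length_class == 3 else "narrow"
            got = truth_class.get(r.tss_ids[0])
            if got is None:
                continue
            n_tot += 1
            n_ok += got == want
        assert n_tot > 0 and n_ok / n_tot >= 0.90


class TestAnchorSortAndClasses:
    def _ndr(self, start, length, chrom="chr1"):
        return nm.NdrRecord(chrom, start, start + length, ["g"], start,
                            "left", "+")

    def test_sort_by_decreasing_length(self):
        ndrs = [self._ndr(0, 100), self._ndr(500, 400), self._ndr(2000, 250)]
        assert [r.length for r in nm.anchor_sort(ndrs)] == [400, 250, 100]

    def test_ties_keep_genomic_order(self):
        ndrs = [self._ndr(2_000, 100), self._ndr(500, 100)]
        assert [r.start for r in nm.anchor_sort(ndrs)] == [500, 2_000]

    def test_empty_sort(self):
        assert nm.anchor_sort([]) == []

    def test_even_tertiles(self):
        ndrs = [self._ndr(i * 1_000, 80 + 60 * i) for i in range(9)]
        nm.length_classes(ndrs, k=3)
        assert [r.length_class for r in ndrs] == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_equal_lengths_deterministic(self):
        ndrs = [self._ndr(i * 1_000, 100) for i in range(6)]
        nm.length_classes(ndrs, k=3)
        assert [r.length_class for r in ndrs] == [1, 1, 2, 2, 3, 3]

    def test_single_class(self):
        ndrs = [self._ndr(0, 100), self._ndr(1_000, 200)]
        nm.length_classes(ndrs, k=1)
        assert all(r.length_class == 1 for r in ndrs)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            nm.length_classes([self._ndr(0, 100)], k=3)


class TestAggregation:
    def _track(self, arr, state="rpm"):
        return nm.CoverageTrack({"chr1": np.asarray(arr, float)}, state, 1)

    def test_constant_track_region_mean(self):
        t = self._track(np.full(1_000, 2.0))
        out = nm.region_means(t, [("chr1", 100, 300), ("chr1", 0, 50)])
        assert np.allclose(out, 2.0)

    def test_step_region_mean(self):
        a = np.zeros(100)
        a[50:] = 4.0
        assert nm.region_means(self._track(a), [("chr1", 0, 100)])[0] == 2.0

    def test_constant_track_constant_matrix(self):
        t = self._track(np.full(4_000, 1.5))
        feats = [AnchoredFeature("f", "chr1", 2_000, "+")]
        m = nm.relative_matrix(t, feats, window=500, bin_width=25)
        assert m.values.shape == (1, 40)
        assert np.allclose(m.values, 1.5)

    def test_minus_orientation_mirrors_profile(self):
        a = np.zeros(4_000)
        a[2_000:] = 1.0  # step exactly at the anchor
        t = self._track(a)
        plus = nm.relative_matrix(
            t, [AnchoredFeature("p", "chr1", 2_000, "+")], 500, 25
        )
        minus = nm.relative_matrix(
            t, [AnchoredFeature("m", "chr1", 2_000, "-")], 500, 25
        )
        assert np.allclose(minus.values[0], plus.values[0][::-1])

    def test_window_bin_mismatch_rejected(self):
        t = self._track(np.zeros(100))
        with pytest.raises(ValueError):
            nm.relative_matrix(t, [], window=500, bin_width=33)

    def test_raw_track_rejected_for_region_means(self):
        with pytest.raises(ValueError):
            nm.region_means(self._track(np.ones(10), "raw"),
                            [("chr1", 0, 5)])

    def test_planted_chip_weight_recovered_as_enrichment(
        self, chip_sim, enrichment_sim
    ):
        """4x planted affinity reads out as mean log2FE >= 1.5 (expect ~2)
        over the target footprints, and the RSC-like factor beats the
        Hmo1-like factor at tDNAs by > 1 log2 unit."""
        model = chip_sim["model"]
        fe = enrichment_sim["log2fe"]["rsc1"]
        targets = [
            (n.chrom, n.dyad - 73, n.dyad + 74)
            for n in model.nucleosomes
            if n.role in ("wide_flank", "tdna_flank")
        ]
        assert nm.region_means(fe, targets).mean() >= 1.5

        genes = model.gene_table()
        tdna = [
            (g.chrom, g.tss - 80, g.tss + 80)
            for g in genes[genes.biotype == "tDNA"].itertuples()
        ]
        rsc = nm.region_means(fe, tdna).mean()
        hmo = nm.region_means(enrichment_sim["log2fe"]["hmo1"], tdna).mean()
        assert rsc - hmo > 1.0
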