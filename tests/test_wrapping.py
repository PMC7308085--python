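"""Protection matrices, species calling, wrapped fraction, end profiles."""

from __future__ import annotations

import numpy as np
import pytest

import nucmap as nm

from oracles import mc_wrapped_fraction


def matrix_of(frags, template_len=174, length_range=(92, 169)):
    return nm.protection_matrix(frags, template_len, length_range)


class TestProtectionMatrix:
    def test_identical_fragments_share_a_cell(self):
        m = matrix_of([(11, 147)] * 3)
        assert m.counts[11, 147 - 92] == 3
        assert m.total() == 3 and m.n_fragments_total == 3

    def test_out_of_range_length_counted_not_binned(self):
        m = matrix_of([(11, 147), (30, 80)])
        assert m.total() == 1
        assert m.n_fragments_total == 2

    def test_empty_matrix_scaling_rejected(self):
        m = matrix_of([])
        assert m.total() == 0
        with pytest.raises(ValueError):
            nm.scale_matrix(m)

    def test_fragment_beyond_template_rejected(self):
        with pytest.raises(ValueError):
            matrix_of([(50, 147)])


class TestScaleMatrix:
    def test_total_equal_n_unchanged(self):
        m = matrix_of([(11, 147)] * 4)
        s = nm.scale_matrix(m, n=4)
        assert np.array_equal(s.counts, m.counts)

    def test_single_cell_scaling_factor(self):
        m = matrix_of([(11, 147)] * 200)
        s = nm.scale_matrix(m, n=100_000)
        assert s.counts[11, 147 - 92] == 100_000.0

    def test_sum_is_exactly_n_without_length_filtering(self):
        rng = np.random.default_rng(1)
        frags = [(int(s), int(l)) for s, l in
                 zip(rng.integers(0, 5, 1_000), rng.integers(92, 170, 1_000))]
        s = nm.scale_matrix(matrix_of(frags), n=100_000)
        assert s.total() == pytest.approx(100_000, abs=1e-6)

    def test_scaling_preserves_proportions(self):
        m = matrix_of([(11, 147)] * 3 + [(23, 135)] * 1)
        s = nm.scale_matrix(m, n=100_000)
        assert s.counts[11, 55] / s.counts[23, 43] == pytest.approx(3.0)

    def test_rescaling_guarded(self):
        s = nm.scale_matrix(matrix_of([(11, 147)]))
        with pytest.raises(ValueError):
            nm.scale_matrix(s)


class TestCallSpecies:
    def _scaled(self, weighted):
        frags = []
        for (s, l), n in weighted:
            frags.extend([(s, l)] * n)
        return nm.scale_matrix(matrix_of(frags))

    def test_five_percent_cutoff(self):
        m = self._scaled([((11, 147), 60), ((23, 135), 30), ((41, 117), 4),
                          ((50, 100), 6)])
        species = nm.call_species(m, cutoff=0.05)
        assert [(s.start, s.length) for s in species] == [
            (11, 147), (23, 135), (50, 100)
        ]  # the 4% cell is below the cutoff

    def test_fractions_invariant_to_scale_n(self):
        frags = [((11, 147), 7), ((23, 135), 3)]
        m1 = nm.scale_matrix(matrix_of(
            [f for fl, n in frags for f in [fl] * n]), n=100_000)
        m2 = nm.scale_matrix(matrix_of(
            [f for fl, n in frags for f in [fl] * n]), n=1_000)
        f1 = [s.fraction for s in nm.call_species(m1)]
        f2 = [s.fraction for s in nm.call_species(m2)]
        assert f1 == pytest.approx(f2)

    def test_single_cell_fraction_one(self):
        species = nm.call_species(self._scaled([((11, 147), 5)]))
        assert len(species) == 1 and species[0].fraction == 1.0
        assert species[0].end_1based == 158

    def test_raising_cutoff_never_adds_species(self):
        m = self._scaled([((11, 147), 50), ((23, 135), 30), ((41, 117), 20)])
        prev = {(s.start, s.length) for s in nm.call_species(m, 0.05)}
        for cutoff in (0.1, 0.25, 0.4, 0.6):
            cur = {(s.start, s.length) for s in nm.call_species(m, cutoff)}
            assert cur <= prev
            prev = cur


class TestWrappedFraction:
    def test_all_full_length(self):
        m = matrix_of([(11, 147)] * 10)
        assert nm.wrapped_fraction(m) == 1.0

    def test_boundary_inclusive_at_135(self):
        m = matrix_of([(11, 147)] * 6 + [(23, 135)] * 3 + [(41, 117)] * 1)
        assert nm.wrapped_fraction(m, min_len=135) == pytest.approx(0.9)

    def test_matrix_equals_fragment_list_statistic(self, protection_run):
        """Matrix-marginal wrapped fraction equals the same statistic
        computed straight from the deduplicated fragment list."""
        matrix = protection_run["matrix"]
        mols = protection_run["molecules"]
        lo, hi = matrix.length_range
        lengths = np.array([r.length for r in mols])
        in_range = lengths[(lengths >= lo) & (lengths <= hi)]
        direct = (in_range >= 135).mean()
        assert nm.wrapped_fraction(matrix) == pytest.approx(direct)

    def test_pipeline_estimate_matches_mc_oracle(self, protection_run):
        """Estimated wrapped fraction after UMI dedup within 0.03 of a
        1e6-draw Monte-Carlo oracle on the generative rules."""
        pcfg = protection_run["pcfg"]
        est = nm.wrapped_fraction(protection_run["matrix"])
        oracle = mc_wrapped_fraction(
            pcfg, 1_000_000, seed=12345,
            length_range=protection_run["matrix"].length_range,
        )
        assert abs(est - oracle) < 0.03


class TestEndProfile:
    def test_shared_fixed_right_end(self):
        m = nm.scale_matrix(matrix_of([(11, 147)] * 5 + [(23, 135)] * 5))
        prof = nm.end_profile(m)
        assert prof.fixed_side == "right"
        assert prof.right.mode == 158  # 11+147 = 23+135
        assert prof.left.mode == 11

    def test_fully_wrapped_only_both_fixed(self):
        m = nm.scale_matrix(matrix_of([(11, 147)] * 5))
        assert nm.end_profile(m).fixed_side == "both"

    def test_uniform_ends_neither_fixed(self):
        frags = [(s, 100) for s in range(0, 70)]
        m = nm.scale_matrix(matrix_of(frags))
        assert nm.end_profile(m).fixed_side == "neither"

    def test_planted_boundary_recovered_within_1bp(self, protection_run):
        """The planted fully-wrapped boundary (1-based 158) survives
        digestion jitter, PCR and dedup to within 1 bp."""
        prof = nm.end_profile(protection_run["matrix"])
        assert prof.fixed_side == "right"
        assert abs(prof.right.mode - 158) <= 1
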