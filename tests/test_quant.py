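"""Frequency conversion, background subtraction, ablation, and the
multi-fiber geometry chain."""

import numpy as np
import pytest

from mitodel.quant import (FrequencyTable, InfeasibleFrequencyError,
                           ablation_at_biopsy, ablation_at_onset,
                           feature_ablation, frequencies, mappability_factor,
                           multi_fiber_boundaries, remaining_fraction_profile,
                           subtract_background)
from mitodel.refmap import DeletionSpan
from tests.conftest import make_catalog

L = 16571


class TestMappability:
    def test_uniform_depth_gives_unity(self):
        depth = np.full(L, 100.0)
        d, low = mappability_factor(depth, DeletionSpan(8471, 13447))
        assert d == 1.0 and not low

    def test_depressed_junction_positions(self):
        depth = np.full(L, 100.0)
        depth[8470] = depth[13446] = 50.0
        d, _ = mappability_factor(depth, DeletionSpan(8471, 13447))
        assert d == pytest.approx(2.0)

    def test_asymmetric_positions_use_their_mean(self):
        depth = np.full(L, 100.0)
        depth[999] = 80.0
        depth[1999] = 120.0
        d, _ = mappability_factor(depth, DeletionSpan(1000, 2000))
        assert d == pytest.approx(1.0)

    def test_zero_depth_capped_and_flagged(self):
        depth = np.full(L, 100.0)
        depth[999] = depth[1999] = 0.0
        d, low = mappability_factor(depth, DeletionSpan(1000, 2000))
        assert d == 10.0 and low


class TestFrequencies:
    def test_no_deletions_all_wildtype(self):
        ft = frequencies(make_catalog([], r_t=1000))
        assert ft.f_u == 1.0 and len(ft.rows) == 0

    def test_hand_computed_single_species(self):
        # L_u 16571, span 4977 (L_i 11594), delta 1, x 10, L_r 150,
        # r_t 100000 -> f = 165710 / 15,049,770
        cat = make_catalog([(8471, 13447, 10)])
        ft = frequencies(cat, anchor_correction=False)
        assert ft.rows["f_i"].iloc[0] == pytest.approx(165710 / 15_049_770)
        assert ft.f_u == pytest.approx(1 - 165710 / 15_049_770)

    def test_bound_holds_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(1, 30)
            rows = []
            for _j in range(n):
                ls5 = int(rng.integers(1, L - 200))
                length = int(rng.integers(1, L - ls5))
                rows.append((ls5, ls5 + length - 1, int(rng.integers(1, 50))))
            ft = frequencies(make_catalog(rows, r_t=200_000))
            assert np.all(ft.rows["f_i"] <= ft.rows["bound"] + 1e-15)
            assert ft.f_u + ft.rows["f_i"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_reads_is_infeasible(self):
        with pytest.raises(InfeasibleFrequencyError):
            frequencies(make_catalog([], r_t=0))


class TestBackground:
    def _table(self, f):
        cat = make_catalog([(1000, 2000, 1)])
        ft = frequencies(cat, anchor_correction=False)
        ft.rows["f_i"] = f
        ft.rows["f_i_bg"] = f
        return ft

    def test_subtraction_arithmetic(self):
        ft = self._table(1e-4)
        ctrl = self._table(1e-5)
        out = subtract_background(ft, ctrl)
        assert out.rows["f_i_bg"].iloc[0] == pytest.approx(9e-5)

    def test_floor_at_zero(self):
        ft = self._table(1e-5)
        ctrl = self._table(1e-4)
        out = subtract_background(ft, ctrl)
        assert out.rows["f_i_bg"].iloc[0] == 0.0

    def test_absent_junction_subtracts_nothing(self):
        ft = self._table(1e-4)
        ctrl = frequencies(make_catalog([(5000, 6000, 3)]))
        out = subtract_background(ft, ctrl)
        assert out.rows["f_i_bg"].iloc[0] == pytest.approx(1e-4)

    def test_no_control_unchanged(self):
        ft = self._table(1e-4)
        out = subtract_background(ft, None)
        assert out.rows["f_i_bg"].iloc[0] == pytest.approx(1e-4)


class TestAblation:
    def _single(self, f=0.01, ls5=8471, hs5=13447):
        ft = frequencies(make_catalog([(ls5, hs5, 1)]), anchor_correction=False)
        ft.rows["f_i"] = f
        ft.rows["f_i_bg"] = f
        return ft

    def test_single_deletion_value(self):
        a = ablation_at_biopsy(self._single())
        assert a == pytest.approx(0.01 * 4977 / L)

    def test_empty_is_zero(self):
        assert ablation_at_biopsy(frequencies(make_catalog([], r_t=10))) == 0.0

    def test_equals_area_above_remaining_curve(self):
        rng = np.random.default_rng(11)
        rows = [(int(a), int(a + ln), 1 + int(rng.integers(20)))
                for a, ln in zip(rng.integers(1, 9000, 12),
                                 rng.integers(10, 6000, 12))]
        ft = frequencies(make_catalog(rows))
        profile = remaining_fraction_profile(ft)
        assert np.mean(1 - profile) == pytest.approx(
            ablation_at_biopsy(ft), abs=1e-9)

    def test_row_order_and_split_invariance(self):
        ft_a = frequencies(make_catalog([(1000, 2000, 6), (3000, 4000, 2)]))
        ft_b = frequencies(make_catalog([(3000, 4000, 2), (1000, 2000, 6)]))
        ft_c = frequencies(make_catalog([(1000, 2000, 3), (1000, 2000, 3),
                                         (3000, 4000, 2)]))
        a = ablation_at_biopsy(ft_a)
        assert ablation_at_biopsy(ft_b) == pytest.approx(a)
        assert ablation_at_biopsy(ft_c) == pytest.approx(a)

    def test_profile_shape_for_one_deletion(self):
        ft = self._single(f=0.1)
        profile = remaining_fraction_profile(ft)
        assert np.allclose(profile[8470:13447], 0.9)
        assert np.allclose(profile[:8470], 1.0)
        assert np.allclose(profile[13447:], 1.0)

    @pytest.mark.parametrize("a,onset,biopsy,expected", [
        (0.10, 30, 60, 0.05),
        (0.10, 60, 60, 0.10),
        (0.023, 35, 62, 0.023 * 35 / 62),
    ])
    def test_onset_projection(self, a, onset, biopsy, expected):
        assert ablation_at_onset(a, onset, biopsy) == pytest.approx(expected)

    def test_onset_after_biopsy_rejected(self):
        with pytest.raises(ValueError):
            ablation_at_onset(0.1, 70, 60)


class TestFeatureAblation:
    def _ft(self, rows):
        ft = frequencies(make_catalog(rows), anchor_correction=False)
        return ft

    def test_non_overlapping_deletion_contributes_nothing(self, fmap):
        ft = self._ft([(14000, 14100, 1)])
        ft.rows["f_i_bg"] = 0.1
        out = feature_ablation(ft, fmap, {"co1": ["CO1"]})
        assert out["per_set"]["co1"] == 0.0

    def test_multiplicative_combination(self, fmap):
        # two deletions each hitting exactly one of two disjoint systems
        ft = self._ft([(6000, 7000, 1), (14800, 15000, 1)])
        ft.rows["f_i_bg"] = [0.1, 0.1]
        out = feature_ablation(ft, fmap, {"co1": ["CO1"], "cytb": ["CYTB"]},
                               combine=True)
        assert out["per_set"]["co1"] == pytest.approx(0.1)
        assert out["per_set"]["cytb"] == pytest.approx(0.1)
        assert out["combined_deficiency"] == pytest.approx(1 - 0.81)

    def test_whole_genome_set_collects_total_mass(self, fmap):
        ft = self._ft([(1000, 2000, 1), (5000, 9000, 1)])
        ft.rows["f_i_bg"] = [0.02, 0.03]
        out = feature_ablation(ft, fmap, {"all": ["major_arc", "minor_arc"]})
        assert out["per_set"]["all"] == pytest.approx(0.05)

    def test_unknown_feature_raises(self, fmap):
        ft = self._ft([(1000, 2000, 1)])
        with pytest.raises(KeyError):
            feature_ablation(ft, fmap, {"bad": ["NOPE"]})


class TestMultiFiberGeometry:
    def test_printed_chain_20mg(self):
        out = multi_fiber_boundaries(20, 1.06, 3630, nuclei_total=380_100)
        assert out["volume_ul"] == pytest.approx(18.9, abs=0.05)
        assert out["face_area_mm2"] == pytest.approx(7.09, abs=0.01)
        assert out["fibers"] == pytest.approx(1950, abs=10)
        assert out["multi_fiber_boundary"] == pytest.approx(5.12e-4, abs=0.01e-4)

    def test_printed_chain_25mg(self):
        out = multi_fiber_boundaries(25, 1.06, 3630, nuclei_total=380_100)
        assert out["fibers"] == pytest.approx(2270, abs=10)
        assert out["nuclei_per_fiber"] == pytest.approx(168, abs=1)

    def test_fiber_area_scaling_law(self):
        a = multi_fiber_boundaries(20, 1.06, 3630)
        b = multi_fiber_boundaries(20, 1.06, 7260)
        assert b["fibers"] == pytest.approx(a["fibers"] / 2)
        assert b["multi_fiber_boundary"] == pytest.approx(
            2 * a["multi_fiber_boundary"])

    def test_mtdna_chain(self):
        out = multi_fiber_boundaries(20, 1.06, 3630, mtdna_total=1.08e9)
        assert out["single_copy_frequency"] == pytest.approx(9.26e-10, rel=1e-2)
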