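"""Bitmaps, change classes, register matrices, down-selection and diversity."""

import itertools

import numpy as np
import pytest

from helpers import downselect_brute_force, make_annotations
from neomotif.genotype_logic import (
    CLASS_I_SLOTS,
    bitmap_class_i,
    bitmap_class_ii,
    classify_binding_change,
    cumulative_fraction_by_ppf,
    downselect,
    exposure_fraction,
    pattern_diversity,
    register_matrix,
)


class TestBitmaps:
    def test_printed_examples(self):
        assert bitmap_class_i([0, 0, 0, 0, 0, 0], True) == "000000"
        assert bitmap_class_i([0, 0, -1.5, 0, 0, 0], True) == "001000"
        assert bitmap_class_i([-1.2, 0, 0, 0, -3, 0], True) == "100010"

    def test_hidden_mutant_zeroes_everything(self):
        assert bitmap_class_i([-5] * 6, False) == "000000"

    def test_class_ii_arity(self):
        assert bitmap_class_ii([-2.0, 0.0], True) == "10"
        with pytest.raises(ValueError):
            bitmap_class_ii([-2.0, 0.0, 1.0], True)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = rng.normal(size=6)
            loose = bitmap_class_i(z, True, threshold=0.0)
            strict = bitmap_class_i(z, True, threshold=-1.0)
            # tightening the cut never turns a 0 into a 1
            assert all(not (s == "1" and l == "0") for s, l in zip(strict, loose))


class TestChangeClass:
    @pytest.mark.parametrize(
        "wt,mut,label",
        [(-1.5, -0.2, "Lost"), (-0.5, -1.5, "Gained"), (-1.2, -1.4, "Retained"),
         (-0.5, -0.7, "Retained")],
    )
    def test_rule(self, wt, mut, label):
        assert classify_binding_change(wt, mut) == label

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        swap = {"Lost": "Gained", "Gained": "Lost", "Retained": "Retained"}
        for _ in range(100):
            wt, mut = rng.normal(size=2) - 1
            assert classify_binding_change(mut, wt) == swap[classify_binding_change(wt, mut)]


class TestRegisterMatrix:
    def test_all_equal_ties_list_everything(self):
        rm = register_matrix(np.zeros((6, 5)))
        assert len(rm.argmin) == 30
        assert rm.dominant == ("A1", 1)

    def test_unique_minimum(self):
        m = np.arange(30, dtype=float).reshape(6, 5)
        m[3, 2] = -9.0
        rm = register_matrix(m)
        assert rm.min_value == -9.0 and rm.argmin == [("B2", 3)]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(6, 5))
        rm = register_matrix(m)
        assert rm.min_value == pytest.approx(m.min())
        i, j = np.unravel_index(np.argmin(m), m.shape)
        assert rm.dominant == (CLASS_I_SLOTS[i], j + 1)

    def test_undefined_cells_excluded(self):
        m = np.full((6, 5), np.nan)
        m[2, 4] = 0.5
        rm = register_matrix(m)
        assert rm.argmin == [("B1", 5)]
        with pytest.raises(ValueError):
            register_matrix(np.full((6, 5), np.nan))


class TestDownselect:
    def test_matches_exhaustive_oracle_on_randomized_case(self):
        rng = np.random.default_rng(3)
        df = make_annotations(rng, n_mutations=20)
        for threshold in (-1.0, -0.5, 0.0):
            table = downselect(df, threshold=threshold)
            nb, ne, nd = downselect_brute_force(df, threshold)
            assert table.n_binding == nb
            assert table.n_binding_and_TCEM_exposed == ne
            assert table.n_binding_TCEM_I_and_II == nd
            assert table.n_9mers == 180 and table.n_peptides_9_15 == 480
            table.validate()

    def test_nothing_binds(self):
        rng = np.random.default_rng(4)
        df = make_annotations(rng, n_mutations=5)
        table = downselect(df, threshold=-50.0)
        assert table.n_binding == 0
        assert table.n_nonbinding_9mers == table.n_9mers

    def test_nested_subsets_hold_under_threshold_sweep(self):
        rng = np.random.default_rng(5)
        df = make_annotations(rng, n_mutations=10)
        prev = None
        for threshold in (-2.0, -1.0, 0.0):
            t = downselect(df, threshold=threshold)
            t.validate()
            if prev is not None:
                assert t.n_binding >= prev.n_binding  # looser cut binds more
            prev = t

    def test_containing_rule_is_stricter_or_equal(self):
        rng = np.random.default_rng(6)
        df = make_annotations(rng, n_mutations=15)
        loose = downselect(df, dual_class_rule="mutation")
        strict = downselect(df, dual_class_rule="containing")
        assert strict.n_binding_TCEM_I_and_II <= loose.n_binding_TCEM_I_and_II


class TestExposureFraction:
    def test_register_uniform_null_near_five_ninths(self):
        from neomotif.synthetic_data import gen_null_register_annotations

        df = gen_null_register_annotations(20_000, seed=7)
        frac = exposure_fraction(df, threshold=-1.0)
        assert frac == pytest.approx(5 / 9, abs=0.02)

    def test_binding_only_at_anchors_gives_zero(self):
        rng = np.random.default_rng(8)
        df = make_annotations(rng, n_mutations=10)
        df9 = df[df.width == 9].copy()
        for s in CLASS_I_SLOTS:
            df9[f"z_mut_{s}"] = np.where(df9.exposed, 1.0, -2.0)
        assert exposure_fraction(df9) == 0.0

    def test_binding_only_when_exposed_gives_one(self):
        rng = np.random.default_rng(9)
        df = make_annotations(rng, n_mutations=10)
        df9 = df[df.width == 9].copy()
        for s in CLASS_I_SLOTS:
            df9[f"z_mut_{s}"] = np.where(df9.exposed, -2.0, 1.0)
        assert exposure_fraction(df9) == 1.0

    def test_no_bound_events_is_nan(self):
        rng = np.random.default_rng(10)
        df = make_annotations(rng, n_mutations=2)
        assert np.isnan(exposure_fraction(df, threshold=-99.0))


class TestPatternDiversity:
    def test_single_pattern(self):
        assert pattern_diversity(["000000"] * 10) == (1, 0.0)

    def test_uniform_four_patterns(self):
        bitmaps = ["000001", "000010", "000100", "001000"] * 25
        n, h = pattern_diversity(bitmaps)
        assert n == 4 and h == pytest.approx(2.0)

    def test_full_enumeration_is_64_patterns_6_bits(self):
        bitmaps = ["".join(bits) for bits in itertools.product("01", repeat=6)]
        n, h = pattern_diversity(bitmaps)
        assert n == 64 and h == pytest.approx(6.0)


class TestCumulativeCurve:
    def test_all_hppf_zero_is_a_step(self):
        rng = np.random.default_rng(11)
        df = make_annotations(rng, n_mutations=10)
        df.loc[df.width == 9, "hppf_mut"] = 0
        curve = cumulative_fraction_by_ppf(df, ppf_cap=5, threshold=0.5)
        assert curve.cumulative_fraction.nunique() == 1
        assert curve.cumulative_fraction.iloc[0] > 0

    def test_nondecreasing_for_any_input(self):
        rng = np.random.default_rng(12)
        df = make_annotations(rng, n_mutations=25)
        curve = cumulative_fraction_by_ppf(df, ppf_cap=10)
        assert (np.diff(curve.cumulative_fraction) >= 0).all()

    def test_uniform_hppf_independent_binding_is_near_linear(self):
        rng = np.random.default_rng(13)
        df = make_annotations(rng, n_mutations=300)
        curve = cumulative_fraction_by_ppf(df, ppf_cap=10)
        frac = curve.cumulative_fraction.to_numpy()
        # increments should be roughly equal under independence
        inc = np.diff(np.concatenate([[0.0], frac]))
        assert inc.std() / inc.mean() < 0.35
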