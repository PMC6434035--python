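"""Dice, repeatability index, ICC(3,1), spatial correlation, ICC fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bhcvr.retest import (
    dice,
    extract_stats,
    icc31,
    icc_fractions,
    overlap_mask,
    repeatability,
    spatial_correlation,
)


def _mask(idx, shape=(4, 4)):
    m = np.zeros(shape, bool)
    for i in idx:
        m[np.unravel_index(i, shape)] = True
    return m


class TestDice:
    def test_identical_masks(self):
        m = _mask([0, 3, 7])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice(_mask([0, 1]), _mask([4, 5])) == 0.0

    def test_hand_enumeration(self):
        a = _mask([0, 1, 2, 3])
        b = _mask([1, 2, 3, 4, 5, 6])
        assert dice(a, b) == pytest.approx(0.6)

    def test_symmetry_and_monotonicity(self):
        a, b = _mask([0, 1, 2, 3]), _mask([2, 3, 4, 5])
        assert dice(a, b) == dice(b, a)
        b_more = _mask([1, 2, 3, 5])  # same size, larger overlap
        assert dice(a, b_more) > dice(a, b)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dice(_mask([]), _mask([]))


class TestRepeatability:
    def test_identical_maps(self):
        m = np.arange(1.0, 17.0).reshape(4, 4)
        idx, nexc = repeatability(m, m, np.ones((4, 4), bool))
        assert idx == 1.0 and nexc == 0

    def test_tripled_map_gives_half(self):
        m = np.arange(1.0, 17.0).reshape(4, 4)
        idx, _ = repeatability(m, 3 * m, np.ones((4, 4), bool))
        assert idx == pytest.approx(0.5)

    def test_negated_map_all_excluded(self):
        m = np.arange(1.0, 17.0).reshape(4, 4)
        with pytest.raises(ValueError, match="excluded"):
            repeatability(m, -m, np.ones((4, 4), bool))

    @given(
        scale=st.floats(0.1, 10.0),
        vals=hnp.arrays(np.float64, 9, elements=st.floats(0.5, 5.0)),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_common_rescaling(self, scale, vals):
        m1 = vals.reshape(3, 3)
        m2 = m1 * 1.3
        mask = np.ones((3, 3), bool)
        a, _ = repeatability(m1, m2, mask)
        b, _ = repeatability(scale * m1, scale * m2, mask)
        assert a == pytest.approx(b)


def _icc_anova_oracle(table):
    """Brute-force two-way ANOVA decomposition for one (n, k) table."""
    n, k = table.shape
    grand = table.mean()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_sess = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    bms = ss_subj / (n - 1)
    ems = (ss_tot - ss_subj - ss_sess) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestIcc31:
    def test_identical_sessions_give_one(self):
        t = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc31(t) == pytest.approx(1.0)

    def test_three_subject_table_matches_oracle(self):
        t = np.array([[1.0, 1.1], [2.0, 2.1], [3.0, 2.9]])
        assert icc31(t) == pytest.approx(_icc_anova_oracle(t), abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(20):
            t = rng.standard_normal((10, 2))
            assert icc31(t) == pytest.approx(_icc_anova_oracle(t), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        t = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "session": np.tile(np.arange(3), 8),
                "y": t.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="session", ratings="y")
        sel = ref["Type"].isin(["ICC3", "ICC(C,1)"])  # label differs by version
        icc3 = float(ref.loc[sel, "ICC"].to_numpy()[0])
        assert icc31(t) == pytest.approx(icc3, abs=1e-8)

    def test_no_subject_effect_near_zero(self, rng):
        t = rng.standard_normal((50, 2, 500))  # 500 independent voxels
        vals = icc31(np.moveaxis(t, -1, 0))
        assert abs(np.mean(vals)) < 0.1

    def test_zero_variance_flagged(self):
        assert np.isnan(icc31(np.ones((4, 2))))

    def test_vectorized_matches_per_voxel(self, rng):
        cube = rng.standard_normal((2, 3, 6, 2))
        out = icc31(cube)
        for i in range(2):
            for j in range(3):
                assert out[i, j] == pytest.approx(_icc_anova_oracle(cube[i, j]))


class TestSpatialCorrelation:
    def test_affine_map_perfect_correlation(self):
        m = np.arange(9.0).reshape(3, 3)
        r, z = spatial_correlation(m, 2 * m + 1, np.ones((3, 3), bool))
        assert r == pytest.approx(1.0)
        assert np.isinf(z)

    def test_fisher_z_of_08(self):
        rng = np.random.default_rng(0)
        # construct maps with exact sample correlation 0.8
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        e = rng.standard_normal(500)
        e -= e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * e
        r, z = spatial_correlation(
            x.reshape(20, 25), y.reshape(20, 25), np.ones((20, 25), bool)
        )
        assert r == pytest.approx(0.8, abs=1e-10)
        assert z == pytest.approx(np.arctanh(0.8), abs=1e-10)
        assert z == pytest.approx(1.0986, abs=1e-4)

    def test_independent_maps_near_zero(self, rng):
        n = 2500
        a = rng.standard_normal(n).reshape(50, 50)
        b = rng.standard_normal(n).reshape(50, 50)
        r, _ = spatial_correlation(a, b, np.ones((50, 50), bool))
        assert abs(r) < 2 / np.sqrt(n)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spatial_correlation(
                np.ones((3, 3)), np.arange(9.0).reshape(3, 3), np.ones((3, 3), bool)
            )


class TestIccFractions:
    def test_extremes(self):
        gm = np.ones((5, 5), bool)
        assert icc_fractions(np.ones((5, 5)), gm) == (1.0, 1.0)
        assert icc_fractions(np.full((5, 5), 0.5), gm) == (1.0, 0.0)

    def test_uniform_distribution_fractions(self, rng):
        vals = rng.uniform(0, 1, 100_000).reshape(1000, 100)
        f04, f06 = icc_fractions(vals, np.ones_like(vals, bool))
        assert f04 == pytest.approx(0.6, abs=0.01)
        assert f06 == pytest.approx(0.4, abs=0.01)


class TestOverlapAndStats:
    def test_subset_overlap(self):
        a, b = _mask([1, 2]), _mask([1, 2, 3, 4])
        np.testing.assert_array_equal(overlap_mask(a, b), a)

    def test_disjoint_stats_flagged(self):
        a, b = _mask([0]), _mask([5])
        ov = overlap_mask(a, b)
        assert not ov.any()
        out = extract_stats(np.ones((4, 4)), {"overlap": ov})
        assert np.isnan(out["overlap"])

    def test_mean_t_hand_average(self):
        t = np.zeros((4, 4))
        t[0, 0], t[0, 1], t[1, 0] = 2.0, 4.0, 6.0
        out = extract_stats(t, {"roi": _mask([0, 1, 4])})
        assert out["roi"] == pytest.approx(4.0)
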