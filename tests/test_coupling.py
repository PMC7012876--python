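import numpy as np
import pytest

from hemosys.coupling import (
    INTERMITTENT,
    MISSING,
    POOR,
    TIGHT,
    category_area_fractions,
    coupling_change_table,
    coupling_maps,
)
from tests.conftest import make_grid


def _series_with_r(target_r, n, rng):
    """Construct (x, y) with Pearson r equal to target_r exactly.

    Mixes an orthonormalized noise vector into x:
    y = r*x + sqrt(1-r^2)*e with x, e unit-norm, zero-mean, orthogonal.
    """
    x = rng.normal(size=n)
    x = x - x.mean()
    x /= np.linalg.norm(x)
    e = rng.normal(size=n)
    e = e - e.mean()
    e -= (e @ x) * x
    e /= np.linalg.norm(e)
    y = target_r * x + np.sqrt(1 - target_r**2) * e
    return x, y


class TestCouplingMaps:
    def test_identical_series_both_windows_is_tight(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=56)
        bf = make_grid(s[None, None, :], variable="BF")
        bv = make_grid(s[None, None, :] * 3.0 + 5.0, variable="BV")
        res = coupling_maps(bf, bv)
        assert res.category[0, 0] == TIGHT
        assert res.r_window1[0, 0] == pytest.approx(1.0)
        assert res.r_window2[0, 0] == pytest.approx(1.0)

    def test_independent_white_noise_is_poor(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bf = make_grid(rng.normal(size=(1, 1, 56)), variable="BF")
            bv = make_grid(rng.normal(size=(1, 1, 56)), variable="BV")
            if coupling_maps(bf, bv).category[0, 0] == POOR:
                hits += 1
        assert hits >= 19  # |r| > 0.7 at n=28 is a far-tail event

    def test_coupled_then_orthogonal_is_intermittent(self):
        t = np.arange(56.0)
        s = np.cos(2 * np.pi * t / 14)
        u = np.cos(2 * np.pi * t / 7)
        bf_series = np.where(t < 28, s, u)
        res = coupling_maps(
            make_grid(bf_series[None, None, :], variable="BF"),
            make_grid(s[None, None, :], variable="BV"),
        )
        assert res.category[0, 0] == INTERMITTENT

    def test_threshold_is_strict(self):
        # r = 1.0 exactly never exceeds a threshold of 1.0
        s = np.random.default_rng(1).normal(size=56)
        res = coupling_maps(
            make_grid(s[None, None, :], variable="BF"),
            make_grid(s[None, None, :], variable="BV"),
            corr_threshold=1.0,
        )
        assert res.category[0, 0] == POOR

    def test_constant_series_is_missing(self):
        bf = make_grid(np.ones((1, 1, 56)), variable="BF")
        bv = make_grid(np.random.default_rng(0).normal(size=(1, 1, 56)), variable="BV")
        res = coupling_maps(bf, bv)
        assert res.category[0, 0] == MISSING
        assert np.isnan(res.r_window1[0, 0])

    def test_classification_invariant_to_affine_rescaling(self, coupling_scene):
        from hemosys import preprocess_stack

        trial, _ = coupling_scene
        bf = preprocess_stack(trial.stacks["BF"])
        bv = preprocess_stack(trial.stacks["BV"])
        base = coupling_maps(bf, bv)
        bf2 = make_grid(bf.values * 4.2 + 17.0, times=bf.times, variable="BF")
        res = coupling_maps(bf2, make_grid(bv.values, times=bv.times, variable="BV"))
        np.testing.assert_array_equal(base.category, res.category)

    def test_swapping_windows_preserves_categories_and_negates_delta(self):
        rng = np.random.default_rng(5)
        values_bf = rng.normal(size=(3, 4, 56)) + 2 * rng.normal(size=(3, 4, 1))
        values_bv = values_bf + 0.8 * rng.normal(size=(3, 4, 56))
        bf, bv = make_grid(values_bf, variable="BF"), make_grid(values_bv, variable="BV")
        fwd = coupling_maps(bf, bv, windows=((0, 28), (28, 56)))
        rev = coupling_maps(bf, bv, windows=((28, 56), (0, 28)))
        np.testing.assert_array_equal(fwd.category, rev.category)
        np.testing.assert_allclose(fwd.delta_r, -rev.delta_r, atol=1e-12)


class TestCouplingChange:
    def test_change_table_is_exact_subtraction(self):
        rng = np.random.default_rng(8)
        x1, y1 = _series_with_r(0.9, 28, rng)
        x2, y2 = _series_with_r(0.4, 28, rng)
        bf = make_grid(np.concatenate([x1, x2])[None, None, :], variable="BF")
        bv = make_grid(np.concatenate([y1, y2])[None, None, :], variable="BV")
        table = coupling_change_table(coupling_maps(bf, bv))
        assert table.loc[0, "r_window1"] == pytest.approx(0.9, abs=1e-9)
        assert table.loc[0, "delta_r"] == pytest.approx(-0.5, abs=1e-9)

    def test_planted_inverse_relationship_has_slope_minus_two(self):
        # plant r2 = 1 - r1 per cell: delta_r = 1 - 2*r1, slope exactly -2
        rng = np.random.default_rng(13)
        r1_values = np.linspace(0.05, 0.95, 12)
        bf_rows, bv_rows = [], []
        for r1 in r1_values:
            x1, y1 = _series_with_r(r1, 28, rng)
            x2, y2 = _series_with_r(1 - r1, 28, rng)
            bf_rows.append(np.concatenate([x1, x2]))
            bv_rows.append(np.concatenate([y1, y2]))
        bf = make_grid(np.asarray(bf_rows).reshape(3, 4, 56), variable="BF")
        bv = make_grid(np.asarray(bv_rows).reshape(3, 4, 56), variable="BV")
        table = coupling_change_table(coupling_maps(bf, bv))
        slope = np.polyfit(table["r_window1"], table["delta_r"], 1)[0]
        assert slope == pytest.approx(-2.0, abs=1e-6)


class TestAreaFractions:
    def test_all_tight_fixture(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(2, 2, 56))
        res = coupling_maps(make_grid(values, variable="BF"), make_grid(values, variable="BV"))
        fractions = category_area_fractions(res)
        assert fractions == {TIGHT: 100.0, POOR: 0.0, INTERMITTENT: 0.0}

    def test_fractions_sum_to_hundred_on_random_fixtures(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            bf = make_grid(rng.normal(size=(4, 5, 56)), variable="BF")
            bv = make_grid(rng.normal(size=(4, 5, 56)), variable="BV")
            fractions = category_area_fractions(coupling_maps(bf, bv))
            assert sum(fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_planted_scene_fractions_match_manifest(self, coupling_scene):
        from hemosys import preprocess_stack

        trial, manifest = coupling_scene
        res = coupling_maps(
            preprocess_stack(trial.stacks["BF"]), preprocess_stack(trial.stacks["BV"])
        )
        truth = np.asarray(manifest["category"])
        fractions = category_area_fractions(res)
        for cat in (TIGHT, POOR, INTERMITTENT):
            planted_pct = 100.0 * (truth == cat).mean()
            assert fractions[cat] == pytest.approx(planted_pct, abs=7.0)
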