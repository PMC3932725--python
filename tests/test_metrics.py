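"""The eleven-metric battery: hand-derived values, invariants, and agreement
with the literal brute-force definitions."""

import itertools

import numpy as np
import pytest

import bruteforce as bf
from metricmine import Image, evaluate_battery
from metricmine.metrics import (
    METRIC_ORDER,
    BatteryConfig,
    DegenerateInputError,
    MetricBattery,
    adi,
    compute_all,
    cor,
    edi,
    mi_family,
    msd,
    ncc,
    woo,
)

from conftest import img


class TestDifferenceMetrics:
    def test_msd_hand_values(self):
        assert msd(img([0, 0, 1, 1]), img([0, 1, 0, 1])).raw_value == pytest.approx(0.5)
        res = msd(img([0, 4]), img([4, 0]))
        assert res.raw_value == pytest.approx(16.0)
        assert res.score == 0.0  # worst case over a dynamic range of 4

    def test_adi_hand_values(self):
        assert adi(img([0, 0, 1, 1]), img([0, 1, 0, 1])).raw_value == pytest.approx(0.5)
        assert adi(img([0, 2, 4]), img([4, 2, 0])).raw_value == pytest.approx(8 / 3)

    def test_identity_pairs_score_one(self, rng):
        r = img(rng.normal(size=20))
        for fn in (msd, adi):
            res = fn(r, r)
            assert res.raw_value == 0.0
            assert res.score == 1.0

    def test_edi_hand_entropy(self):
        res = edi(img([0, 0, 1, 1]), img([0, 1, 0, 1]), bins=3)
        assert res.raw_value == pytest.approx(1.5)
        assert res.score == pytest.approx(1 - 1.5 / np.log2(3))

    def test_edi_constant_difference_scores_one(self, rng):
        r = img(rng.normal(size=12))
        s = Image(r.voxels + 3.7)  # constant offset: difference has no entropy
        res = edi(r, s)
        assert res.raw_value == 0.0
        assert res.score == 1.0

    def test_edi_uniform_difference_scores_zero(self):
        res = edi(img([0, 1, 2, 3]), img([0, 0, 0, 0]), bins=4)
        assert res.raw_value == pytest.approx(2.0)
        assert res.score == pytest.approx(0.0)


class TestMIFamily:
    def test_perfect_dependence(self):
        fam = mi_family(img([0, 0, 1, 1]), img([0, 0, 1, 1]), bins=(2, 2))
        assert fam["mif"].raw_value == pytest.approx(1.0)
        assert fam["nmi"].raw_value == pytest.approx(2.0)
        assert fam["red"].raw_value == pytest.approx(0.5)
        assert fam["uni"].raw_value == pytest.approx(0.0)
        assert fam["aum"].raw_value == pytest.approx(0.0)
        assert all(fam[m].score == pytest.approx(1.0) for m in fam)

    def test_independence(self):
        fam = mi_family(img([0, 0, 1, 1]), img([0, 1, 0, 1]), bins=(2, 2))
        assert fam["mif"].raw_value == pytest.approx(0.0)
        assert fam["nmi"].raw_value == pytest.approx(1.0)
        assert all(fam[m].score == pytest.approx(0.0) for m in fam)

    @pytest.mark.parametrize("seed", range(10))
    def test_printed_algebraic_identities(self, seed):
        """uni = 2 - (H_R+H_S)/H_RS and red = 1 - H_RS/(H_R+H_S)."""
        rng = np.random.default_rng(seed)
        r = img(rng.integers(0, 6, size=30).astype(float))
        s = img(rng.integers(0, 6, size=30).astype(float))
        fam = mi_family(r, s, bins=(8, 8))
        h_r = fam["mif"].info["H_R"]
        h_s = fam["mif"].info["H_S"]
        h_rs = fam["mif"].info["H_RS"]
        assert fam["uni"].raw_value == pytest.approx(2 - (h_r + h_s) / h_rs, abs=1e-12)
        assert fam["red"].raw_value == pytest.approx(1 - h_rs / (h_r + h_s), abs=1e-12)

    def test_both_constant_identical_scores_one(self):
        fam = mi_family(img([2.0, 2.0]), img([2.0, 2.0]))
        assert all(f.score == 1.0 and f.degenerate for f in fam.values())

    def test_both_constant_different_scores_zero(self):
        fam = mi_family(img([2.0, 2.0]), img([3.0, 3.0]))
        assert all(f.score == 0.0 and f.degenerate for f in fam.values())


class TestConditionalMetrics:
    def test_ncc_hand_value(self):
        assert ncc(img([1, 2, 3, 4]), img([1, 2, 4, 3])).raw_value == pytest.approx(0.8)

    def test_ncc_linear_and_anticorrelated(self, rng):
        r = img(rng.normal(size=16))
        assert ncc(r, Image(2 * r.voxels + 1)).score == pytest.approx(1.0)
        assert ncc(r, Image(-r.voxels)).score == pytest.approx(0.0)

    def test_ncc_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ncc(img([1.0, 1.0]), img([0, 1]))

    def test_cor_hand_value(self):
        assert cor(img([0, 0, 1, 1]), img([1, 3, 2, 2])).raw_value == pytest.approx(0.0)

    def test_cor_functional_dependence(self):
        assert cor(img([0, 0, 1, 1]), img([5, 5, 3, 3])).raw_value == pytest.approx(1.0)

    def test_cor_constant_reference_is_zero(self):
        assert cor(img([1.0] * 4), img([1, 2, 3, 4])).raw_value == pytest.approx(0.0)

    def test_cor_constant_candidate_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cor(img([0, 1, 0, 1]), img([2.0] * 4))

    def test_woo_hand_values(self):
        assert woo(img([0, 0, 1, 1]), img([5, 5, 3, 3])).raw_value == pytest.approx(1.0)
        assert woo(img([0, 0, 1, 1]), img([1, 3, 2, 2])).raw_value == pytest.approx(0.75)

    def test_woo_large_spread_clamps_to_zero(self):
        # single level with mu=1, sigma=2: sigma/mu = 2 > 1, so raw = -1
        res = woo(img([0, 0, 0, 0]), img([-1, 3, -1, 3]))
        assert res.raw_value < 0
        assert res.score == 0.0

    def test_woo_near_zero_means_skipped(self):
        res = woo(img([0, 0, 1, 1]), img([0, 0, 3, 5]))
        assert res.info["skipped_levels"] == 1
        assert res.raw_value == pytest.approx(1 - 2 * 1 / 4 / 4)

    def test_woo_all_levels_skipped_degenerate(self):
        with pytest.raises(DegenerateInputError):
            woo(img([0, 1, 0, 1]), img([0.0] * 4))


class TestBatteryInvariants:
    def test_identity_scores_all_one(self, phantom):
        results = compute_all(phantom, phantom)
        for name, res in results.items():
            assert res.score == pytest.approx(1.0, abs=1e-9), name

    @pytest.mark.parametrize("seed", range(25))
    def test_identity_scores_one_random_images(self, seed):
        rng = np.random.default_rng(seed)
        r = img(np.round(rng.uniform(0, 10, size=24), 1))
        for name, res in compute_all(r, r).items():
            assert res.score == pytest.approx(1.0, abs=1e-9), name

    @pytest.mark.parametrize("seed", range(15))
    def test_symmetric_metrics_are_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        r = img(rng.integers(0, 8, size=30).astype(float))
        s = img(rng.integers(0, 8, size=30).astype(float))
        a = compute_all(r, s)
        b = compute_all(s, r)
        for name in ("msd", "adi", "edi", "mif", "nmi", "ncc", "red", "uni", "aum"):
            assert a[name].raw_value == pytest.approx(b[name].raw_value, abs=1e-12), name

    def test_cor_and_woo_labelled_asymmetric(self):
        # conditioning is on the reference; swapping arguments changes them
        r = img([0, 0, 1, 1, 2, 2])
        s = img([1, 3, 2, 2, 4, 0])
        assert cor(r, s).raw_value != pytest.approx(cor(s, r).raw_value)

    def test_scores_in_unit_interval_random_pairs(self):
        """>=200 randomized pairs: every defined score lies in [0,1]."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            r = img(rng.uniform(-5, 5, size=16))
            s = img(rng.uniform(-5, 5, size=16))
            for name, res in compute_all(r, s).items():
                if not np.isnan(res.score):
                    assert 0.0 <= res.score <= 1.0, name


def _oracle_compare(r_vals, s_vals, config):
    """Assert package metrics equal the brute-force definitions at 1e-9."""
    r, s = img(list(r_vals)), img(list(s_vals))
    got = compute_all(r, s, config)
    r_vals, s_vals = list(map(float, r_vals)), list(map(float, s_vals))

    assert got["msd"].raw_value == pytest.approx(bf.msd_raw(r_vals, s_vals), abs=1e-9)
    assert got["msd"].score == pytest.approx(bf.msd_score(r_vals, s_vals), abs=1e-9)
    assert got["adi"].raw_value == pytest.approx(bf.adi_raw(r_vals, s_vals), abs=1e-9)
    assert got["adi"].score == pytest.approx(bf.adi_score(r_vals, s_vals), abs=1e-9)
    assert got["edi"].raw_value == pytest.approx(
        bf.edi_raw(r_vals, s_vals, config.diff_bins), abs=1e-9
    )
    assert got["edi"].score == pytest.approx(
        bf.edi_score(r_vals, s_vals, config.diff_bins), abs=1e-9
    )

    r_const = min(r_vals) == max(r_vals)
    s_const = min(s_vals) == max(s_vals)
    if r_const and s_const:
        expected = 1.0 if r_vals == s_vals else 0.0
        for m in ("mif", "nmi", "red", "uni", "aum"):
            assert got[m].score == expected
    else:
        fam = bf.mi_family_values(r_vals, s_vals, config.bins)
        for m, (raw, score) in fam.items():
            if raw is not None:
                assert got[m].raw_value == pytest.approx(raw, abs=1e-9), m
            assert got[m].score == pytest.approx(score, abs=1e-9), m

    expect_ncc = bf.ncc_raw(r_vals, s_vals)
    if expect_ncc is None:
        assert got["ncc"].degenerate
    else:
        assert got["ncc"].raw_value == pytest.approx(expect_ncc, abs=1e-9)

    expect_cor = bf.cor_raw(r_vals, s_vals)
    if expect_cor is None:
        assert got["cor"].degenerate
    else:
        assert got["cor"].raw_value == pytest.approx(expect_cor, abs=1e-9)

    expect_woo = bf.woo_raw(r_vals, s_vals, eps=config.eps)
    if expect_woo is None:
        assert got["woo"].degenerate
    else:
        assert got["woo"].raw_value == pytest.approx(expect_woo, abs=1e-9)


class TestOracleEquivalence:
    def test_exhaustive_small_images(self):
        """All ordered pairs of 4-voxel images over 3 intensity levels agree
        with the brute-force definitions (6561 pairs, every metric)."""
        config = BatteryConfig(bins=8, diff_bins=8)
        images = list(itertools.product([0.0, 1.0, 2.0], repeat=4))
        for r_vals in images:
            for s_vals in images:
                _oracle_compare(r_vals, s_vals, config)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_eight_voxel_pairs(self, seed):
        """Seeded sweep of 8-voxel, 4-level pairs against the definitions."""
        config = BatteryConfig(bins=8, diff_bins=8)
        rng = np.random.default_rng(seed)
        for _ in range(75):
            r_vals = rng.integers(0, 4, size=8).astype(float)
            s_vals = rng.integers(0, 4, size=8).astype(float)
            _oracle_compare(list(r_vals), list(s_vals), config)


class TestBattery:
    def test_identity_candidate_row_of_ones(self, phantom):
        table = evaluate_battery(phantom, [phantom])
        assert table.scores.shape == (1, 11)
        np.testing.assert_allclose(table.scores.to_numpy(), 1.0, atol=1e-9)

    def test_synthetic_candidates_full_table(self, small_candidate_set):
        cset = small_candidate_set
        table = evaluate_battery(cset.reference, cset.candidates, ids=cset.run_ids)
        assert table.scores.shape == (8, 11)
        assert list(table.scores.columns) == list(METRIC_ORDER)
        assert not table.scores.isna().any().any()

    def test_shape_mismatch_names_candidate(self, phantom):
        bad = Image(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="candidate/0001"):
            evaluate_battery(phantom, [phantom, bad])

    def test_degenerate_cells_marked_missing(self, phantom):
        flat = Image(np.full(phantom.shape, 0.5))
        table = evaluate_battery(phantom, [flat])
        assert table.degenerate.loc["candidate/0000", "ncc"]
        assert np.isnan(table.scores.loc["candidate/0000", "ncc"])

    def test_estimator_transform_matches_function(self, small_candidate_set):
        cset = small_candidate_set
        est = MetricBattery().fit(cset.reference)
        direct = evaluate_battery(cset.reference, cset.candidates)
        np.testing.assert_allclose(
            est.transform(cset.candidates).to_numpy(), direct.scores.to_numpy()
        )

    def test_csv_round_trip(self, tmp_path, small_candidate_set):
        cset = small_candidate_set
        table = evaluate_battery(cset.reference, cset.candidates, ids=cset.run_ids)
        table.to_csv(tmp_path / "scores.csv", tmp_path / "raws.csv")
        from metricmine.metrics import MetricTable

        back = MetricTable.from_csv(tmp_path / "scores.csv", tmp_path / "raws.csv")
        np.testing.assert_allclose(back.scores.to_numpy(), table.scores.to_numpy())
        np.testing.assert_allclose(back.raws.to_numpy(), table.raws.to_numpy())


@pytest.mark.parametrize("n_levels", [20])
def test_consistent_metric_scores_decrease_with_severity(n_levels):
    """Seed-averaged mean score over the nine consensus metrics falls as the
    planted perturbation severity grows (20 levels x 10 seeds)."""
    from scipy.stats import spearmanr

    from metricmine import evaluate_battery, make_candidate_set, make_phantom
    from metricmine.mining import CONSISTENT_METRICS

    severities = np.linspace(0, 1, n_levels)
    curves = []
    for seed in range(10):
        ref = make_phantom((16, 16, 8), seed=seed)
        cset = make_candidate_set(ref, n=n_levels, severity_grid=list(severities), seed=seed + 500)
        t = evaluate_battery(cset.reference, cset.candidates, ids=cset.run_ids)
        curves.append(t.scores[list(CONSISTENT_METRICS)].mean(axis=1).to_numpy())
    mean_curve = np.mean(curves, axis=0)
    rho = spearmanr(severities, mean_curve).correlation
    assert rho <= -0.98
    assert mean_curve[0] > mean_curve[-1]
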