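"""Category weights, stratified split, candidate regressions and metrics."""

import numpy as np
import pytest

from mangroveheight import (GLOBAL_CATEGORY_COUNTS, GridTransform, RasterTile,
                            apply_calibration, compute_category_weights,
                            evaluate_metrics, fit_candidates, make_model,
                            select_model, stratified_split)
from mangroveheight.calibration import (LinearHeightModel, SqrtLinearHeightModel,
                                        assign_categories, weights_for)


def heights_with_counts(counts):
    """One representative height per category, repeated `count` times."""
    reps = []
    for c, n in enumerate(counts):
        reps.append(np.full(n, 10.0 * c + 5.0))
    return np.concatenate(reps)


def test_category_assignment_half_open_bins():
    idx = assign_categories([0.0, 9.999, 10.0, 49.9, 50.0, 120.0])
    np.testing.assert_array_equal(idx, [0, 0, 1, 4, 5, 5])


def test_weights_are_reciprocal_of_six_times_count():
    counts = (40, 25, 10, 5, 3, 2)
    table = compute_category_weights(heights_with_counts(counts))
    for c, n in enumerate(counts):
        assert table.loc[c, "n_points"] == n
        assert table.loc[c, "weight"] == pytest.approx(1.0 / (n * 6))


def test_weight_mass_per_category_is_one_sixth():
    counts = (1000, 300, 55, 7, 3, 1)
    table = compute_category_weights(heights_with_counts(counts))
    mass = table["n_points"] * table["weight"]
    np.testing.assert_allclose(mass, 1 / 6)
    assert mass.sum() == pytest.approx(1.0)


def test_single_point_categories_all_weight_one_sixth():
    table = compute_category_weights(heights_with_counts((1,) * 6))
    np.testing.assert_allclose(table["weight"], 1 / 6)


def test_empty_categories_excluded():
    table = compute_category_weights([5.0, 5.0, 25.0])
    assert set(table.index) == {0, 2}
    with pytest.raises(ValueError, match="absent"):
        weights_for([15.0], table)


def test_global_reference_weights_match_printed_values():
    """Weights of the published global corpus reproduce the printed table
    to within one unit of the last printed digit."""
    table = compute_category_weights(heights_with_counts(GLOBAL_CATEGORY_COUNTS))
    printed = [(0.0000001087, 1e-10), (0.000000232, 1e-9), (0.00000115, 1e-8),
               (0.0000084, 1e-7), (0.000244, 1e-6), (0.0030, 1e-4)]
    for c, (p, ulp) in enumerate(printed):
        assert abs(table.loc[c, "weight"] - p) <= ulp


def test_global_reference_counts_sum_to_corpus_total():
    assert sum(GLOBAL_CATEGORY_COUNTS) == 2_414_652


def test_split_sizes_follow_floor_rule():
    y = heights_with_counts((10, 1, 0, 0, 0, 0))
    train, valid = stratified_split(y, 0.7, seed=0)
    cat = assign_categories(y)
    assert (cat[train] == 0).sum() == 7 and (cat[valid] == 0).sum() == 3
    # a single-member category: floor(0.7*1)=0 to train, 1 to validation
    assert (cat[train] == 1).sum() == 0 and (cat[valid] == 1).sum() == 1
    assert sorted(np.concatenate([train, valid])) == list(range(11))


def test_split_deterministic_in_seed():
    y = np.random.default_rng(0).uniform(0, 55, 500)
    t1, v1 = stratified_split(y, 0.7, seed=5)
    t2, v2 = stratified_split(y, 0.7, seed=5)
    t3, _ = stratified_split(y, 0.7, seed=6)
    np.testing.assert_array_equal(t1, t2)
    assert not np.array_equal(t1, t3)


def test_split_rejects_bad_fraction():
    with pytest.raises(ValueError):
        stratified_split([1.0, 2.0], frac=1.5)


def test_sqrt_model_recovers_generating_coefficients_exactly():
    """Noiseless data built as (1.02 sqrt(x) + 0.33)^2 is recovered to 6+ dp."""
    x = np.linspace(0.1, 55, 400)
    y = (1.02 * np.sqrt(x) + 0.33) ** 2
    m = SqrtLinearHeightModel().fit(x, y)
    assert m.a_ == pytest.approx(1.02, abs=1e-9)
    assert m.b_ == pytest.approx(0.33, abs=1e-9)
    assert m.metrics_.rmse == pytest.approx(0.0, abs=1e-9)


def test_candidates_rank_correctly_on_linear_truth():
    x = np.linspace(0.5, 50, 300)
    y = 2 * x + 1
    models = fit_candidates(x, y)
    best = select_model(models)
    assert best.form == "linear"
    assert best.a_ == pytest.approx(2.0) and best.b_ == pytest.approx(1.0)
    sqrt_m = next(m for m in models if m.form == "sqrt_linear")
    assert sqrt_m.metrics_.rmse > best.metrics_.rmse


def test_uniform_weights_equal_unweighted_fit():
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 50, 200)
    y = 1.5 * x + rng.normal(0, 2, 200)
    a = LinearHeightModel().fit(x, y)
    b = LinearHeightModel().fit(x, y, sample_weight=np.full(200, 0.37))
    assert a.a_ == pytest.approx(b.a_)
    assert a.b_ == pytest.approx(b.b_)


def test_weighted_fit_follows_the_weights():
    # two clusters with conflicting slopes: weights decide the fit
    x = np.concatenate([np.full(50, 10.0), np.full(50, 40.0)])
    y = np.concatenate([np.full(50, 10.0), np.full(50, 20.0)])
    w_lo = np.concatenate([np.full(50, 1.0), np.full(50, 1e-9)])
    m = LinearHeightModel().fit(x, y, w_lo)
    assert m.predict([10.0])[0] == pytest.approx(10.0, abs=1e-3)


def test_degenerate_x_raises():
    with pytest.raises(ValueError, match="distinct"):
        LinearHeightModel().fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


def test_model_selection_tiebreaks():
    def with_metrics(rmse, mae, bias, corr):
        m = make_model("linear", 1, 0)
        from mangroveheight.calibration import FitMetrics
        m.metrics_ = FitMetrics(corr=corr, mae=mae, rmse=rmse, bias=bias)
        return m

    a = with_metrics(2.4, 1.9, 0.5, 0.9)
    b = with_metrics(3.0, 1.0, 0.0, 0.99)
    assert select_model([b, a]) is a          # lowest RMSE wins
    c = with_metrics(2.4, 2.1, 0.0, 0.99)
    assert select_model([c, a]) is a          # RMSE tie -> lower MAE
    with pytest.raises(ValueError):
        select_model([])


@pytest.mark.parametrize("x, expected", [(0.0, 0.1089), (25.0, 29.4849)])
def test_published_coefficients_evaluate_correctly(x, expected):
    m = make_model("sqrt_linear", 1.02, 0.33)
    assert m.predict([x])[0] == pytest.approx(expected, abs=1e-12)


def test_apply_calibration_identity_and_nodata(meter_grid):
    dem = meter_grid([[4.0, -9999.0], [25.0, 0.0]])
    out = apply_calibration(make_model("linear", 1.0, 0.0), dem)
    np.testing.assert_array_equal(out.values, dem.values)
    out2 = apply_calibration(make_model("sqrt_linear", 1.02, 0.33), dem)
    assert out2.values[0, 1] == dem.nodata
    assert out2.values[1, 0] == pytest.approx((1.02 * 5 + 0.33) ** 2)


def test_apply_calibration_rejects_negative_heights(meter_grid):
    with pytest.raises(ValueError, match="negative"):
        apply_calibration(make_model("sqrt_linear", 1.02, 0.33),
                          meter_grid([[-3.0]]))


def test_calibration_monotone_increasing(meter_grid):
    m = make_model("sqrt_linear", 1.02, 0.33)
    x = np.linspace(0, 60, 100)
    pred = m.predict(x)
    assert np.all(np.diff(pred) > 0)


def test_metrics_textbook_cases():
    m = evaluate_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.rmse, m.mae, m.bias) == (0.0, 0.0, 0.0)
    assert m.corr == pytest.approx(1.0)
    shifted = evaluate_metrics([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
    assert (shifted.bias, shifted.mae, shifted.rmse) == (2.0, 2.0, 2.0)
    assert shifted.corr == pytest.approx(1.0)


def test_metrics_match_formula_oracle():
    rng = np.random.default_rng(44)
    p, o = rng.normal(size=100), rng.normal(size=100)
    m = evaluate_metrics(p, o)
    r = p - o
    assert m.mae == pytest.approx(np.abs(r).mean(), abs=1e-12)
    assert m.rmse == pytest.approx(np.sqrt((r**2).mean()), abs=1e-12)
    assert m.bias == pytest.approx(r.mean(), abs=1e-12)
    sp, so = p - p.mean(), o - o.mean()
    assert m.corr == pytest.approx(np.sum(sp * so)
                                   / np.sqrt(np.sum(sp**2) * np.sum(so**2)), abs=1e-12)
    assert m.rmse >= m.mae >= 0


def test_metrics_require_two_points():
    with pytest.raises(ValueError):
        evaluate_metrics([1.0], [1.0])


def test_model_json_roundtrip(tmp_path):
    from mangroveheight.calibration import load_model, save_model
    m = make_model("sqrt_linear", 1.02, 0.33)
    save_model(m, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert back.form == "sqrt_linear"
    assert back.predict([25.0])[0] == pytest.approx(m.predict([25.0])[0])
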