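"""Model-layer contracts: splits, metrics, chain training, harness ops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vnqi.model import (
    ChainSpec,
    FEATURES,
    evaluate,
    fit_baseline,
    fit_chain,
    learning_curve,
    pearson_ranking,
    predict_vnqi,
    split_dataset,
    stability_analysis,
)


# ---------------------------------------------------------------- splits


def test_split_sizes_and_exhaustiveness(feature_table):
    df = feature_table.copy()
    df["oxy_v"] = 0.5
    df["oxy_t"] = 0.5
    train, test = split_dataset(df, 0.8, seed=0)
    assert len(train) == 160 and len(test) == 40
    assert set(train.sample_id) | set(test.sample_id) == set(df.sample_id)
    assert set(train.sample_id) & set(test.sample_id) == set()

    # same seed -> identical membership
    train2, _ = split_dataset(df, 0.8, seed=0)
    assert list(train.sample_id) == list(train2.sample_id)

    small = df.iloc[:10]
    tr, te = split_dataset(small, 0.8, seed=3)
    assert len(tr) == 8 and len(te) == 2

    with pytest.raises(ValueError):
        split_dataset(df, 1.2, seed=0)
    with pytest.raises(ValueError):
        split_dataset(df.iloc[:5], 0.8, seed=0)


def test_split_500_gives_400_100(cohort_records):
    train, test = split_dataset(cohort_records, 0.8, seed=1)
    assert len(train) == 400 and len(test) == 100


# ---------------------------------------------------------------- evaluate


def test_evaluate_perfect_and_hand_case():
    rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rep.r2 == 1.0 and rep.mae == 0.0 and rep.mse == 0.0 and rep.rmse == 0.0

    rep = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert rep.mae == pytest.approx(2.0 / 3.0)
    assert rep.mse == pytest.approx(2.0 / 3.0)
    assert rep.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
    assert rep.r2 == pytest.approx(0.0)
    np.testing.assert_allclose(rep.residuals, [-1.0, 0.0, 1.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_evaluate_matches_brute_force(seed):
    """All four metrics agree with direct residual arithmetic to 1e-10."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 50))
    y = rng.normal(size=n)
    p = rng.normal(size=n)
    rep = evaluate(y, p)
    res = y - p
    sse = float(np.sum(res**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    assert rep.mae == pytest.approx(np.mean(np.abs(res)), abs=1e-10)
    assert rep.mse == pytest.approx(sse / n, abs=1e-10)
    assert rep.rmse == pytest.approx(np.sqrt(sse / n), abs=1e-10)
    if sst > 0:
        assert rep.r2 == pytest.approx(1.0 - sse / sst, abs=1e-10)


def test_evaluate_zero_variance_r2_undefined():
    with pytest.warns(UserWarning, match="zero variance"):
        rep = evaluate([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
    assert rep.r2 is None
    assert rep.mae > 0


# ---------------------------------------------------------------- chain fit


def test_chain_recovers_constant_labels(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.5
    df["oxy_t"] = 0.5
    chain = fit_chain(df, fast_spec)
    pred = chain.predict(df[FEATURES].to_numpy(dtype=float))
    assert np.all(np.abs(pred - 0.5) <= 0.01)


def test_chain_learns_exact_linear_relation(feature_table, fast_spec):
    """With labels an exact linear map of coverage, the chain matches the
    least-squares oracle on held-out data."""
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    train, test = split_dataset(df, 0.8, seed=0)
    chain = fit_chain(train, fast_spec)
    pred = chain.predict(test[FEATURES].to_numpy(dtype=float))
    rep = evaluate(test["oxy_t"], pred)
    assert rep.r2 >= 0.99
    # least-squares oracle is exact here; the chain tracks it closely
    beta = np.polyfit(train["vessel_coverage"], train["oxy_t"], 1)
    ls_pred = np.polyval(beta, test["vessel_coverage"])
    assert np.max(np.abs(pred - ls_pred)) < 0.02


def test_chain_training_is_deterministic(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    train, test = split_dataset(df, 0.8, seed=0)
    a = fit_chain(train, fast_spec)
    b = fit_chain(train, fast_spec)
    assert a.manifest["nn1_architecture"] == b.manifest["nn1_architecture"]
    assert a.manifest["nn2_architecture"] == b.manifest["nn2_architecture"]
    X = test[FEATURES].to_numpy(dtype=float)
    np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-12)


def test_teacher_forcing_uses_oracle_oxy_v(feature_table, fast_spec):
    """NN2's seventh-input statistics match the oracle oxy_v column even
    when NN1 cannot predict it (oxy_v is pure noise here)."""
    rng = np.random.default_rng(7)
    df = feature_table.copy()
    df["oxy_v"] = rng.uniform(0, 1, len(df))  # unlearnable from morphology
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    train, held = df.iloc[:150], df.iloc[150:]
    chain = fit_chain(train, fast_spec)
    assert chain.manifest["nn2_train_oxy_v_source"] == "oracle"
    assert chain.scaler7.mean_[6] == pytest.approx(train["oxy_v"].mean())
    assert chain.scaler7.scale_[6] == pytest.approx(train["oxy_v"].std(ddof=0))
    # inference substitutes NN1's prediction; on held-out rows it cannot
    # track the unlearnable noise labels
    v_hat = chain.predict_oxy_v(held[FEATURES].to_numpy(dtype=float))
    corr = np.corrcoef(v_hat, held["oxy_v"])[0, 1]
    assert np.isnan(corr) or abs(corr) < 0.5


def test_scalers_fit_on_training_data_only(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    train, _ = split_dataset(df, 0.8, seed=0)
    chain = fit_chain(train, fast_spec)
    np.testing.assert_allclose(
        chain.scaler6.mean_, train[FEATURES].to_numpy(dtype=float).mean(axis=0)
    )


def test_predict_vnqi_always_in_unit_interval(feature_table, fast_spec):
    """Even far outside the training envelope the score stays in [0, 1]."""
    df = feature_table.copy()
    df["oxy_v"] = np.clip(0.8 + 0.5 * df["vessel_coverage"], 0, 1)
    df["oxy_t"] = np.clip(0.9 + 0.5 * df["vessel_coverage"], 0, 1)
    chain = fit_chain(df, fast_spec)
    extreme = df[FEATURES].to_numpy(dtype=float) * 50 - 10
    out = chain.predict(extreme)
    assert np.all(out >= 0.0) and np.all(out <= 1.0)
    # scalar path, including a MorphologyMetrics-like dict
    one = {k: float(df[k].iloc[0]) for k in FEATURES}
    val = predict_vnqi(chain, one)
    assert 0.0 <= val <= 1.0


def test_predict_vnqi_rejects_unfitted_chain():
    class Hollow:
        pass

    with pytest.raises(ValueError, match="not fitted"):
        predict_vnqi(Hollow(), {k: 0.0 for k in FEATURES})


def test_missing_values_rejected(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.5
    df["oxy_t"] = 0.5
    df.loc[3, "vessel_coverage"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_chain(df, fast_spec)


# ---------------------------------------------------------------- baselines


def test_baseline_identity_relation(feature_table, fast_spec):
    """oxy_t == oxy_v exactly: the augmented model reduces to a copy."""
    df = feature_table.copy()
    df["oxy_v"] = 0.2 + 0.6 * df["vessel_coverage"]
    df["oxy_t"] = df["oxy_v"]
    train, test = split_dataset(df, 0.8, seed=0)
    model = fit_baseline(train, "oxy_t_with_true_oxy_v", fast_spec)
    pred = model.predict(
        test[FEATURES].to_numpy(dtype=float), oxy_v=test["oxy_v"].to_numpy()
    )
    rep = evaluate(test["oxy_t"], pred)
    assert rep.r2 >= 0.999
    # the direct-copy oracle
    assert np.max(np.abs(pred - test["oxy_v"].to_numpy())) < 0.01


def test_multi_output_constant_labels(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.4
    df["oxy_t"] = 0.6
    model = fit_baseline(df, "multi_output", fast_spec)
    pred = model.predict(df[FEATURES].to_numpy(dtype=float))
    assert pred.shape == (len(df), 2)
    assert np.all(np.abs(pred[:, 0] - 0.4) < 0.02)
    assert np.all(np.abs(pred[:, 1] - 0.6) < 0.02)


def test_unknown_variant_rejected(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.5
    df["oxy_t"] = 0.5
    with pytest.raises(ValueError, match="unknown variant"):
        fit_baseline(df, "bogus", fast_spec)
    model = fit_baseline(df, "oxy_t_with_true_oxy_v", fast_spec)
    with pytest.raises(ValueError, match="needs the true oxy_v"):
        model.predict(df[FEATURES].to_numpy(dtype=float))


# ---------------------------------------------------------------- pearson


def test_pearson_trivial_correlations(feature_table):
    df = feature_table.iloc[:3].copy()
    df["vessel_coverage"] = [1.0, 2.0, 3.0]
    df["oxy_t"] = [2.0, 4.0, 6.0]
    df["oxy_v"] = [0.1, 0.2, 0.3]
    tab = pearson_ranking(df, vnqi=np.array([3.0, 2.0, 1.0]), target="oxy_t")
    tab = tab.set_index("variable")["pearson_r"]
    assert tab["vessel_coverage"] == pytest.approx(1.0)
    assert tab["VNQI"] == pytest.approx(-1.0)


def test_pearson_constant_column_is_nan(feature_table):
    df = feature_table.iloc[:5].copy()
    df["segment_count"] = 7.0
    df["oxy_t"] = np.linspace(0.2, 0.8, 5)
    df["oxy_v"] = np.linspace(0.2, 0.8, 5)
    tab = pearson_ranking(df, vnqi=df["oxy_t"].to_numpy(), target="oxy_t")
    tab = tab.set_index("variable")["pearson_r"]
    assert np.isnan(tab["segment_count"])


def test_pearson_grouped_shape(feature_table):
    df = feature_table.iloc[:20].copy()
    df["oxy_t"] = np.linspace(0.1, 0.9, 20)
    df["oxy_v"] = np.linspace(0.1, 0.9, 20)
    df["group"] = ["a"] * 10 + ["b"] * 10
    tab = pearson_ranking(df, vnqi=df["oxy_t"].to_numpy(), target="oxy_t", group="group")
    assert set(tab["group"]) == {"a", "b"}
    assert (tab.groupby("group").size() == 7).all()  # six metrics + VNQI


# ------------------------------------------------------- stability / curve


def test_stability_identical_seeds_give_zero_sd(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    out = stability_analysis(df, fast_spec, n_partitions=3, split_seeds=[5, 5, 5])
    for col in ("r2_std", "mae_std", "mse_std", "rmse_std"):
        assert np.allclose(out[col], 0.0)
    assert set(out["network"]) == {"NN1", "NN2"}
    assert out.shape[1] == 9  # network + 4 metrics x (mean, std)


def test_stability_near_deterministic_on_noiseless_table(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    out = stability_analysis(df, fast_spec, n_partitions=4)
    assert (out["r2_std"] <= 0.02).all()
    with pytest.raises(ValueError):
        stability_analysis(df, fast_spec, n_partitions=1)


def test_learning_curve_trivial_and_errors(feature_table, fast_spec):
    df = feature_table.copy()
    df["oxy_v"] = 0.3 + 0.5 * df["vessel_coverage"]
    df["oxy_t"] = 0.2 + 0.6 * df["vessel_coverage"]
    out = learning_curve(df, fast_spec, sizes=[160], split_seed=0)
    assert len(out) == 1 and out.loc[0, "size"] == 160
    with pytest.raises(ValueError):
        learning_curve(df, fast_spec, sizes=[])
    with pytest.raises(ValueError):
        learning_curve(df, fast_spec, sizes=[10_000])
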