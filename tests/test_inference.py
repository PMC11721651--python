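"""The three inference stages: mixed models, forest, importance, ICE."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from resogest.inference import (
    ArousalModel,
    CrescendoModel,
    ResonanceForest,
    classification_fit_metrics,
    fit_crescendo,
    fit_resonance_forest,
)
from resogest.simulate import SimConfig

from conftest import make_tables


@pytest.fixture(scope="module")
def synth_tables():
    cfg = SimConfig(
        n_recordings=5, stories_per_recording=3, gestures_per_story=(8, 18),
        crescendo_slope=1.5, arousal_slope=2.0, seed=7,
    )
    return make_tables(cfg)


def _covariate_frame(n, rng):
    return pd.DataFrame({
        "SZ": rng.integers(0, 2, n), "FO": rng.integers(0, 2, n),
        "CV": rng.integers(0, 2, n), "SL": rng.integers(0, 2, n),
        "HO": rng.integers(0, 2, n), "MA": rng.integers(0, 2, n),
        "ND": rng.integers(0, 2, n),
        "G_quote": rng.integers(0, 2, n),
        "Sentiment": rng.uniform(-1, 1, n),
        "protagonist": rng.choice(["narrator", "third-person"], n),
        "group_compose": rng.choice(["all-female", "all-male", "mixed"], n),
        "group_size": rng.choice([2, 3], n),
        "recency": rng.choice(["recent", "distant"], n),
    })


# ---------------------------------------------------------------------------
# crescendo model


def test_crescendo_requires_enough_data(synth_tables):
    table, _, _ = synth_tables
    with pytest.raises(ValueError, match="10 gestures"):
        CrescendoModel(table.head(5))
    one_group = table[table["narrator_id"] == table["narrator_id"].iloc[0]]
    one_group = one_group[
        one_group["recording_id"] == one_group["recording_id"].iloc[0]
    ]
    with pytest.raises(ValueError, match="2 narrator groups"):
        CrescendoModel(one_group)


def test_crescendo_constant_response_degenerate(synth_tables):
    table, _, _ = synth_tables
    flat = table.copy()
    flat["G_expressivity"] = 0.25
    res = fit_crescendo(flat)
    assert res.degenerate
    assert res.fe_params["G_position_rel"] == 0.0
    assert res.pseudo_r2_conditional is None


def test_crescendo_fits_and_reports(synth_tables):
    table, _, _ = synth_tables
    res = fit_crescendo(table)
    assert res.fe_params["G_position_rel"] > 0
    assert res.lrt.statistic >= 0
    assert 0.0 <= res.pseudo_r2_conditional <= 1.0
    assert res.lrt.llf_full >= res.lrt.llf_null - 1e-6
    assert set(res.group_slopes.index) == set(
        (table["recording_id"] + ":" + table["narrator_id"]).unique()
    )
    assert "LRT" in res.summary()


def test_crescendo_lrt_invariant_to_predictor_rescaling(synth_tables):
    """Affine rescaling of the position covariate leaves the LRT
    statistic unchanged (up to optimizer tolerance)."""
    table, _, _ = synth_tables
    res1 = fit_crescendo(table)
    rescaled = table.copy()
    rescaled["G_position_rel"] = 3.0 * rescaled["G_position_rel"] - 1.0
    res2 = fit_crescendo(rescaled)
    assert res2.lrt.statistic == pytest.approx(
        res1.lrt.statistic, abs=1e-3, rel=1e-3
    )


# ---------------------------------------------------------------------------
# arousal model


def test_arousal_single_class_outcome_rejected(synth_tables):
    _, resp, _ = synth_tables
    allno = resp.copy()
    allno["EDA_specific"] = 0
    with pytest.raises(ValueError, match="single class"):
        ArousalModel(allno)


def test_arousal_recovers_positive_effect(synth_tables):
    _, resp, _ = synth_tables
    res = ArousalModel(resp).fit()
    assert res.fe_params["G_expressivity"] > 0
    assert res.lrt.statistic >= 0
    assert 0.0 <= res.pseudo_r2_conditional <= 1.0
    assert set(res.sigmas.index) == {"participant", "recording"}
    assert "Laplace" in res.summary()


# ---------------------------------------------------------------------------
# forest mechanics


def test_forest_missing_predictor_named():
    rng = np.random.default_rng(0)
    df = _covariate_frame(50, rng).drop(columns=["Sentiment"])
    df["EDA_G_resonance"] = rng.integers(0, 2, 50)
    with pytest.raises(ValueError, match="Sentiment"):
        ResonanceForest(df)


def test_forest_deterministic_given_seed():
    rng = np.random.default_rng(1)
    df = _covariate_frame(120, rng)
    df["EDA_G_resonance"] = (df["Sentiment"] > 0).astype(int)
    runs = []
    for _ in range(2):
        res = fit_resonance_forest(df, seed=11, n_trees=60)
        imp = res.permutation_importance(n_repeats=3, seed=11)
        runs.append((res.oob_accuracy, imp["importance"].tolist()))
    assert runs[0] == runs[1]


def test_forest_null_outcome_near_baseline():
    """With the outcome independent of every predictor, OOB accuracy sits
    near the majority-class baseline and the binomial fit test is not
    significant."""
    rng = np.random.default_rng(2)
    df = _covariate_frame(250, rng)
    df["EDA_G_resonance"] = (rng.random(250) < 0.3).astype(int)
    res = fit_resonance_forest(df, seed=0, n_trees=200)
    assert res.binom_pvalue > 0.05
    assert abs(res.oob_accuracy - res.baseline_rate) < 0.12


def test_forest_planted_signal_ranks_first():
    rng = np.random.default_rng(3)
    df = _covariate_frame(200, rng)
    df["EDA_G_resonance"] = df["HO"].astype(int)
    res = fit_resonance_forest(df, seed=0, n_trees=150)
    imp = res.permutation_importance(n_repeats=5, seed=0)
    assert imp.loc[0, "predictor"] == "HO"
    assert res.oob_accuracy > 0.95


def test_forest_constant_column_importance_exactly_zero():
    rng = np.random.default_rng(4)
    df = _covariate_frame(100, rng)
    df["const"] = 1.0
    df["EDA_G_resonance"] = df["SZ"].astype(int)
    res = ResonanceForest(
        df, predictors=["SZ", "FO", "const"], n_trees=80, seed=0
    ).fit()
    imp = res.permutation_importance(n_repeats=3, seed=0)
    assert imp.set_index("predictor").loc["const", "importance"] == 0.0


# ---------------------------------------------------------------------------
# fit metrics


def test_metrics_perfect_probabilistic_prediction():
    y = np.array([0, 1, 1, 0, 1])
    m = classification_fit_metrics(y, y.astype(float), y)
    assert m["r2_traditional"] == pytest.approx(1.0)
    assert m["accuracy"] == 1.0


def test_metrics_constant_base_rate_gives_zero_mcfadden():
    y = np.array([0, 0, 1, 1, 1, 0, 1, 0, 1, 1])
    p = np.full(10, y.mean())
    m = classification_fit_metrics(y, p, (p >= 0.5).astype(int))
    assert m["r2_mcfadden"] == pytest.approx(0.0, abs=1e-9)


def test_metrics_degenerate_sst_flagged():
    y = np.ones(6)
    m = classification_fit_metrics(y, np.full(6, 0.9), np.ones(6, int))
    assert m["r2_traditional"] is None


def test_metrics_binomial_p_equals_tail_enumeration():
    """On a hand-built 10-case prediction set the exact one-tailed p-value
    equals the binomial tail sum."""
    y = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0])
    pred = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 1])  # 8 of 10 correct
    m = classification_fit_metrics(y, pred.astype(float), pred)
    base = 0.6
    tail = sum(
        comb(10, k) * base ** k * (1 - base) ** (10 - k)
        for k in range(8, 11)
    )
    assert m["binom_pvalue"] == pytest.approx(tail, rel=1e-12)


# ---------------------------------------------------------------------------
# ICE curves


@pytest.fixture(scope="module")
def planted_forest():
    rng = np.random.default_rng(5)
    df = _covariate_frame(150, rng)
    df["EDA_G_resonance"] = (df["Sentiment"] > 0).astype(int)
    res = fit_resonance_forest(df, seed=0, n_trees=100)
    return df, res


def test_ice_identity_with_direct_prediction(planted_forest):
    df, res = planted_forest
    probe = df.iloc[[3, 17, 40]]
    direct = res.predict_proba(probe)
    for row_pos, (_, row) in enumerate(probe.iterrows()):
        ice = res.ice_curves("Sentiment", grid=[row["Sentiment"]])
        probe_curve = ice.values[df.index.get_indexer(probe.index), 0]
        assert probe_curve[row_pos] == pytest.approx(
            direct[row_pos], abs=1e-12
        )


def test_ice_mean_equals_partial_dependence(planted_forest):
    """The per-grid-point mean of ICE curves equals sklearn's brute-force
    partial dependence for the same estimator."""
    from sklearn.inspection import partial_dependence

    df, res = planted_forest
    ice = res.ice_curves("Sentiment", n_grid=8)
    model = res.model
    j = list(model._X.columns).index("Sentiment")
    pd_ref = partial_dependence(
        model._clf, model._X.values, [j], method="brute",
        custom_values={j: np.asarray(ice.grid, dtype=float)},
    )
    assert ice.pdp == pytest.approx(pd_ref["average"][0], abs=1e-12)


def test_ice_step_follows_planted_threshold(planted_forest):
    _, res = planted_forest
    ice = res.ice_curves("Sentiment", grid=np.array([-0.8, -0.4, 0.4, 0.8]))
    assert ice.pdp[:2].max() < 0.3
    assert ice.pdp[2:].min() > 0.7


def test_ice_unknown_predictor_rejected(planted_forest):
    _, res = planted_forest
    with pytest.raises(ValueError, match="unknown"):
        res.ice_curves("nonesuch")


def test_ice_categorical_levels(planted_forest):
    df, res = planted_forest
    ice = res.ice_curves("group_compose")
    assert ice.categorical
    assert set(ice.grid) == {"all-female", "all-male", "mixed"}
    assert ice.values.shape == (len(df), 3)


def test_interaction_probe_triads_amplify_kinematic_effect():
    """When cross-participant coupling is stronger in triads than dyads,
    the mean ICE slope of a kinematic component is larger in the triad
    stratum."""
    frames = []
    for size, seed in ((2, 0), (3, 1)):
        cfg = SimConfig.detection_recovery(
            n_recordings=8, stories_per_recording=3,
            gestures_per_story=(12, 24), group_size=size,
            arousal_slope=4.0, arousal_intercept=-1.5,
            coupling_by_group_size={2: 0.1, 3: 0.85},
            crescendo_slope=0.5, participant_arousal_sd=0.3,
            recording_arousal_sd=0.2, seed=seed,
        )
        table, _, _ = make_tables(cfg)
        frames.append(table)
    table = pd.concat(frames, ignore_index=True)
    res = fit_resonance_forest(table, seed=0, n_trees=400)
    ice = res.ice_curves("SZ", grid=np.array([0.0, 1.0]))
    slope = ice.values[:, 1] - ice.values[:, 0]
    sizes = table["group_size"].values
    assert slope[sizes == 3].mean() > slope[sizes == 2].mean()
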