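"""Smoothing, binning, matrix assembly and the reference-fitted PCA."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import tabletbio as tb
from tabletbio.constructs import BinnedFeatureMatrix
from tabletbio.features import FeatureSeries
from tabletbio.registry import matrix_columns


def series(t, v, name="f"):
    return FeatureSeries(name, np.asarray(t, float), np.asarray(v, float))


# --- smoothing ---------------------------------------------------------------


def test_smooth_window_one_is_identity():
    s = series([0, 1, 2], [3.0, -1.0, 7.0])
    out = tb.smooth_series(s, 1)
    np.testing.assert_array_equal(out.values, s.values)


def test_smooth_constant_unchanged():
    s = series(np.arange(10), np.full(10, 4.2))
    for w in (1, 3, 10):
        np.testing.assert_allclose(tb.smooth_series(s, w).values, 4.2)


def test_smooth_causal_mean_hand_computed():
    out = tb.smooth_series(series([0, 1], [0.0, 10.0]), 2)
    np.testing.assert_allclose(out.values, [0.0, 5.0])
    out3 = tb.smooth_series(series([0, 1, 2, 3], [0, 10, 20, 30.0]), 2)
    np.testing.assert_allclose(out3.values, [0, 5, 15, 25.0])


def test_smooth_rejects_bad_window():
    with pytest.raises(ValueError):
        tb.smooth_series(series([0], [1.0]), 0)


# --- binning -----------------------------------------------------------------


def test_bin_constant_series_conserved():
    t = np.linspace(0, 10, 500)
    vals, missing = tb.bin_series(series(t, np.full(500, 3.3)), duration=10)
    assert vals.shape == (100,)
    np.testing.assert_allclose(vals, 3.3)
    assert not missing.any()


def test_bin_single_observation_fills_everywhere():
    vals, missing = tb.bin_series(series([5.0], [2.5]), duration=10)
    np.testing.assert_allclose(vals, 2.5)
    assert not missing.any()


def test_bin_ramp_monotone():
    t = np.linspace(0, 1, 5000)
    vals, _ = tb.bin_series(series(t, t), duration=1)
    assert (np.diff(vals) > 0).all()
    assert vals[0] < 0.02 and vals[-1] > 0.98


def test_bin_empty_series_all_missing():
    vals, missing = tb.bin_series(series([], []), duration=10)
    assert missing.all()
    vals, missing = tb.bin_series(series([1.0], [np.nan]), duration=10)
    assert missing.all()


def test_bin_final_edge_closed_and_interior_interpolated():
    # observations only in bins 10 and 90 (duration 100 -> bin width 1)
    vals, _ = tb.bin_series(series([10.5, 90.5, 100.0], [0.0, 80.0, 80.0]), duration=100)
    assert vals[10] == pytest.approx(0.0)
    assert vals[50] == pytest.approx(40.0)  # linear between bins 10 and 90
    assert vals[0] == pytest.approx(0.0)  # leading carried
    assert vals[99] == pytest.approx(80.0)  # t == duration lands in final bin
    with pytest.raises(ValueError):
        tb.bin_series(series([0.0], [1.0]), duration=0)


# --- matrix assembly ---------------------------------------------------------


def test_matrix_shapes(small_cohort):
    cohort, _ = small_cohort
    n = len(cohort.participants)
    m = tb.assemble_matrix(cohort.challenges, "Connect", "multimodal")
    assert m.values.shape == (n * 6, 1600)
    eye = tb.assemble_matrix(cohort.challenges, "Connect", "eye")
    assert eye.values.shape == (n * 6, 400)
    rocket = tb.assemble_matrix(cohort.challenges, "Rocket", "touch")
    assert rocket.values.shape == (n * 11, 500)
    assert list(m.values.columns) == matrix_columns("multimodal")


def test_matrix_input_order_invariant(small_cohort):
    cohort, _ = small_cohort
    m1 = tb.assemble_matrix(cohort.challenges, "Connect")
    m2 = tb.assemble_matrix(list(reversed(cohort.challenges)), "Connect")
    pd.testing.assert_frame_equal(m1.values, m2.values)


def test_missing_challenge_gives_masked_row(small_cohort, caplog):
    import logging

    cohort, _ = small_cohort
    pid = cohort.participants[0].participant_id
    pruned = [
        c for c in cohort.challenges
        if not (c.participant_id == pid and c.game == "Connect" and c.challenge_index == 3)
    ]
    with caplog.at_level(logging.WARNING, logger="tabletbio"):
        m = tb.assemble_matrix(pruned, "Connect")
    row = m.missing.loc[(pid, "Connect", 3)]
    assert row.all()
    assert any("missing" in msg for msg in caplog.messages)


def test_matrix_csv_roundtrip(tmp_path, small_cohort):
    cohort, _ = small_cohort
    m = tb.assemble_matrix(cohort.challenges, "Connect", "eye")
    tb.constructs.write_matrix(m, tmp_path / "m.csv")
    back = tb.constructs.read_matrix(tmp_path / "m.csv", "Connect", "eye")
    np.testing.assert_allclose(
        back.values.to_numpy(), m.values.to_numpy(), rtol=1e-12
    )


# --- PCA fit and projection --------------------------------------------------


def low_rank_matrix(n_rows=40, n_cols=200, seed=4):
    """Rows built from 3 orthogonal patterns plus small noise."""
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.normal(size=(n_cols, 3)))[0].T
    weights = rng.normal(size=(n_rows, 3)) * [6.0, 3.0, 1.5]
    X = weights @ basis + rng.normal(scale=0.02, size=(n_rows, n_cols))
    cols = matrix_columns("eye", n_cols // 4)
    mi = pd.MultiIndex.from_tuples(
        [(f"p{i:03d}", "Connect", 1 + i % 6) for i in range(n_rows)],
        names=("participant_id", "game", "challenge_index"),
    )
    vals = pd.DataFrame(X, index=mi, columns=cols)
    return BinnedFeatureMatrix(
        values=vals,
        missing=pd.DataFrame(False, index=mi, columns=cols),
        game="Connect",
        modality="eye",
    )


def test_fit_reference_concentrates_on_three_components():
    m = low_rank_matrix()
    model = tb.fit_reference(m, n_components=3)
    assert model.explained_variance_ratio.sum() > 0.95
    assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()


def test_eigenvectors_orthonormal_and_fit_deterministic():
    m = low_rank_matrix()
    model1 = tb.fit_reference(m)
    model2 = tb.fit_reference(m)
    gram = model1.components @ model1.components.T
    np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
    np.testing.assert_array_equal(model1.components, model2.components)
    for comp in model1.components:  # sign convention
        assert comp[np.argmax(np.abs(comp))] > 0


def test_zero_variance_column_dropped_and_recorded():
    m = low_rank_matrix()
    col = m.values.columns[7]
    m.values[col] = 1.234
    model = tb.fit_reference(m)
    assert col in model.dropped_columns
    scores = tb.project(model, m)
    assert np.isfinite(scores.scores.to_numpy()).all()


def test_projection_identity_on_training_matrix():
    """Projecting the reference itself gives uncorrelated scores whose
    variances equal the model's component variances."""
    m = low_rank_matrix()
    model = tb.fit_reference(m)
    scores = tb.project(model, m).scores.to_numpy()
    cov = np.cov(scores, rowvar=False)
    np.testing.assert_allclose(cov, np.diag(model.explained_variance), atol=1e-6)


def test_projecting_reference_mean_row_is_zero():
    m = low_rank_matrix()
    model = tb.fit_reference(m)
    mean_row = m.values.mean(axis=0)
    mi = m.values.index[:1]
    one = BinnedFeatureMatrix(
        values=pd.DataFrame(
            [mean_row.to_numpy()], index=mi, columns=m.values.columns
        ),
        missing=pd.DataFrame(False, index=mi, columns=m.values.columns),
        game="Connect",
        modality="eye",
    )
    scores = tb.project(model, one).scores.to_numpy()
    np.testing.assert_allclose(scores, 0.0, atol=1e-10)


def test_column_mismatch_rejected():
    m = low_rank_matrix()
    model = tb.fit_reference(m)
    # a permuted-column matrix is rejected at construction already
    with pytest.raises(ValueError):
        dataclasses.replace(
            m,
            values=m.values[list(m.values.columns[::-1])],
            missing=m.missing[list(m.missing.columns[::-1])],
        )
    # a model fitted on other columns is rejected at projection
    other = tb.fit_reference(low_rank_matrix(n_cols=100))
    with pytest.raises(ValueError, match="columns"):
        tb.project(other, m)


def test_reference_transfer_no_target_leakage(small_cohort, small_reference):
    """Target-cohort permutation/subsetting never changes projections:
    standardisation and eigenvectors come from the reference only."""
    cohort, _ = small_cohort
    reference, _ = small_reference
    ref_matrix = tb.assemble_matrix(reference.challenges, "Connect", "eye")
    model = tb.fit_reference(ref_matrix)
    full = tb.project(model, tb.assemble_matrix(cohort.challenges, "Connect", "eye"))
    keep = {cohort.participants[0].participant_id, cohort.participants[1].participant_id}
    subset_challenges = [c for c in cohort.challenges if c.participant_id in keep]
    sub = tb.project(model, tb.assemble_matrix(subset_challenges, "Connect", "eye"))
    pd.testing.assert_frame_equal(
        full.scores.loc[sub.scores.index], sub.scores, check_exact=False, rtol=1e-12
    )


def test_model_json_roundtrip(tmp_path):
    m = low_rank_matrix()
    model = tb.fit_reference(m)
    model.save(tmp_path / "model.json")
    back = tb.ConstructModel.load(tmp_path / "model.json")
    np.testing.assert_allclose(back.components, model.components, rtol=1e-15)
    np.testing.assert_allclose(back.means, model.means, rtol=1e-15)
    assert back.columns == model.columns


def test_too_few_rows_rejected():
    m = low_rank_matrix(n_rows=2)
    with pytest.raises(ValueError):
        tb.fit_reference(m, n_components=3)
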