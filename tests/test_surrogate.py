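"""Tree-ensemble surrogates: split bookkeeping, determinism, accuracy."""

import numpy as np
import pytest

from gencat.benchmark import LandscapeParams, emit_reaction_table, make_landscape
from gencat.chemspace import FingerprintConfig
from gencat.reactions import ReactionRecord
from gencat.surrogate import (
    DESCRIPTOR,
    DESCRIPTOR_COMPONENTS,
    SELECTIVITY,
    SELECTIVITY_COMPONENTS,
    coerce_cocatalyst_for_descriptor,
    evaluate_out_of_sample,
    load_ensemble,
    out_of_fold_report,
    predict,
    predict_many,
    prepare_training_records,
    save_ensemble,
    train_ensemble,
)

SMALL_CFG = FingerprintConfig(n_bits=128, component_order=SELECTIVITY_COMPONENTS)
FAST = {"n_estimators": 20}


@pytest.fixture(scope="module")
def table():
    ls = make_landscape(3, LandscapeParams(noise_sigma_ddg=0.2))
    return emit_reaction_table(ls, 120, 4)


def test_cocatalyst_coercion():
    assert coerce_cocatalyst_for_descriptor("OC(=O)c1ccccc1") == "CC(=O)O"
    assert coerce_cocatalyst_for_descriptor("O=C(Cl)C") == "O=C(Br)c1ccccc1"
    assert coerce_cocatalyst_for_descriptor(None) is None
    assert coerce_cocatalyst_for_descriptor("c1ccccc1") is None


def test_cinchona_rows_dropped_for_descriptor_only():
    quinine = "COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1"
    rows = [
        ReactionRecord("NCCc1c[nH]c2ccccc12", "O=CC", quinine, ddg=1.0,
                       descriptor=5.0).completed(),
        ReactionRecord("NCCc1c[nH]c2ccccc12", "O=CC", "O=C(NC)NC", ddg=1.0,
                       descriptor=5.0).completed(),
    ]
    assert len(prepare_training_records(rows, SELECTIVITY)) == 2
    assert len(prepare_training_records(rows, DESCRIPTOR)) == 1


def test_split_bookkeeping(table):
    ens = train_ensemble(table[:30], SELECTIVITY, config=SMALL_CFG, seed=0,
                         n_splits=2, xgb_params=FAST)
    assert len(ens.members) == 2
    for m in ens.members:
        assert len(m.train_idx) == 27 and len(m.test_idx) == 3
        assert not set(m.train_idx) & set(m.test_idx)


def test_training_determinism(table):
    kw = dict(config=SMALL_CFG, seed=5, n_splits=4, xgb_params=FAST)
    r1 = out_of_fold_report(train_ensemble(table, SELECTIVITY, **kw), table)
    r2 = out_of_fold_report(train_ensemble(table, SELECTIVITY, **kw), table)
    assert np.array_equal(r1.oof_predictions, r2.oof_predictions, equal_nan=True)


def test_too_few_records_rejected(table):
    with pytest.raises(ValueError, match=">= 20"):
        train_ensemble(table[:10], SELECTIVITY, config=SMALL_CFG)


def test_constant_targets_give_zero_spread(table):
    from dataclasses import replace

    rows = [replace(r, ddg=1.5, er=None, ee=None).completed() for r in table[:30]]
    ens = train_ensemble(rows, SELECTIVITY, config=SMALL_CFG, seed=0,
                         n_splits=3, xgb_params=FAST)
    res = predict(ens, rows[0])
    assert res.std == pytest.approx(0.0, abs=1e-7)
    assert res.mean == pytest.approx(1.5, abs=1e-6)


def test_memorizing_ensemble_interpolates(table):
    """Noise-free targets, deep trees, training on all rows: training-row
    predictions reproduce the truth closely."""
    ls = make_landscape(3, LandscapeParams(noise_sigma_ddg=0.0))
    rows = emit_reaction_table(ls, 80, 4)
    ens = train_ensemble(rows, SELECTIVITY, config=SMALL_CFG, seed=0, n_splits=3,
                         train_fraction=0.99,
                         xgb_params={"n_estimators": 300, "max_depth": 8,
                                     "learning_rate": 0.3})
    mu, _ = predict_many(ens, rows[:20])
    truth = np.array([r.ddg for r in rows[:20]])
    assert np.median(np.abs(mu - truth)) < 0.1


def test_member_order_irrelevant(table):
    ens = train_ensemble(table, SELECTIVITY, config=SMALL_CFG, seed=1,
                         n_splits=4, xgb_params=FAST)
    res = predict(ens, table[0])
    ens.members = ens.members[::-1]
    res_rev = predict(ens, table[0])
    assert res.mean == pytest.approx(res_rev.mean, abs=1e-12)
    assert res.std == pytest.approx(res_rev.std, abs=1e-12)


def test_out_of_sample_metrics(table):
    ens = train_ensemble(table, SELECTIVITY, config=SMALL_CFG, seed=0,
                         n_splits=3, xgb_params=FAST)
    rep = evaluate_out_of_sample(ens, table[:20])
    # constant-predictor oracle: MAE of the mean prediction vs target
    manual = np.mean(np.abs(rep.oof_predictions - [r.ddg for r in table[:20]]))
    assert rep.mae == pytest.approx(manual, abs=1e-12)
    assert rep.mae**2 <= rep.mse + 1e-12
    with pytest.raises(ValueError, match="empty"):
        evaluate_out_of_sample(ens, [])


def test_perfect_predictions_give_zero_error():
    from gencat.surrogate import CVReport

    # degenerate check through the report arithmetic itself
    y = np.array([1.0, 2.0, 3.0])
    err = y - y
    rep = CVReport(float(np.mean(np.abs(err))), float(np.mean(err**2)), y, np.ones(3))
    assert rep.mae == 0.0 and rep.mse == 0.0


def test_oof_mae_bound_on_synthetic_landscape():
    """Out-of-fold MAE stays within 2.5x the observation noise (sigma=0.2)."""
    ls = make_landscape(1, LandscapeParams(noise_sigma_ddg=0.2))
    rows = emit_reaction_table(ls, 500, 2)
    ens = train_ensemble(
        rows, SELECTIVITY,
        config=FingerprintConfig(n_bits=512, component_order=SELECTIVITY_COMPONENTS),
        seed=0, n_splits=10, xgb_params={"n_estimators": 80},
    )
    rep = out_of_fold_report(ens, rows)
    assert rep.mae <= 0.5


def test_oof_mae_shrinks_with_sample_size():
    ls = make_landscape(1, LandscapeParams(noise_sigma_ddg=0.2))
    maes = []
    for n in (100, 300, 1000):
        rows = emit_reaction_table(ls, n, 7)
        ens = train_ensemble(rows, SELECTIVITY, config=SMALL_CFG, seed=0,
                             n_splits=6, xgb_params={"n_estimators": 60})
        maes.append(out_of_fold_report(ens, rows).mae)
    assert maes[2] < maes[0]
    assert maes[1] <= maes[0] + 0.05  # monotone within noise


def test_save_load_roundtrip(tmp_path, table):
    ens = train_ensemble(table, DESCRIPTOR,
                         config=FingerprintConfig(
                             n_bits=128, component_order=DESCRIPTOR_COMPONENTS),
                         seed=2, n_splits=3, xgb_params=FAST)
    mu, sd = predict_many(ens, table[:10])
    save_ensemble(ens, tmp_path / "model")
    back = load_ensemble(tmp_path / "model")
    mu2, sd2 = predict_many(back, table[:10])
    assert np.array_equal(mu, mu2)
    assert np.array_equal(sd, sd2)
    assert back.target == DESCRIPTOR
    assert back.config == ens.config
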