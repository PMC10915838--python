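"""Fingerprint-based tree-ensemble surrogates for selectivity and activity.

Two regressors drive the genetic optimization: one predicts the
enantioselectivity ddG (kcal/mol) of a catalyst/substrate combination from
experiment-derived tables, the other the activity descriptor (the relative
energy of intermediate 2, kcal/mol).  Both use concatenated Morgan
fingerprints as the reaction representation and an ensemble of XGBoost
regressors trained on repeated random 90/10 splits (100 by default); a
prediction is the mean over members and its uncertainty the member spread.
Averaging the test-fold predictions of the same scheme yields out-of-fold
error estimates (MAE/MSE) without a separate hold-out.

For the descriptor target, reactions catalyzed by cinchona alkaloids are
excluded (different mechanism) and the co-catalyst is coerced to a
three-level encoding: any carboxylic acid is modelled as acetic acid, any
acyl/benzoyl halide as benzoyl bromide, otherwise none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xgboost as xgb
from rdkit import Chem

from .chemspace import FingerprintConfig, featurize_reaction
from .reactions import ReactionRecord, is_cinchona

SELECTIVITY = "selectivity"
DESCRIPTOR = "descriptor"

SELECTIVITY_COMPONENTS = ("catalyst", "cocatalyst", "sub_a", "sub_b", "solvent")
DESCRIPTOR_COMPONENTS = ("catalyst", "cocatalyst", "sub_a", "sub_b")

ACETIC_ACID = "CC(=O)O"
BENZOYL_BROMIDE = "O=C(Br)c1ccccc1"

_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_ACYL_HALIDE = Chem.MolFromSmarts("[CX3](=O)[F,Cl,Br,I]")


def coerce_cocatalyst_for_descriptor(smiles: str | None) -> str | None:
    """Map a co-catalyst to the {AcOH, BzBr, none} encoding."""
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable co-catalyst SMILES {smiles!r}")
    if mol.HasSubstructMatch(_CARBOXYLIC_ACID):
        return ACETIC_ACID
    if mol.HasSubstructMatch(_ACYL_HALIDE):
        return BENZOYL_BROMIDE
    return None


class _LoadedBooster:
    """Minimal predict-only wrapper around a deserialized Booster."""

    def __init__(self, booster: xgb.Booster):
        self.booster = booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.booster.inplace_predict(np.asarray(X, dtype=np.float32))


@dataclass(frozen=True)
class EnsembleMember:
    model: object  # fitted XGB(RF)Regressor or _LoadedBooster
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SurrogateEnsemble:
    """A repeated-split ensemble of tree regressors for one target."""

    target: str
    config: FingerprintConfig
    members: list[EnsembleMember]
    n_splits: int
    train_fraction: float
    seed: int
    booster: str = "gbtree"  # or "rf" (random-forest mode)
    train_targets: np.ndarray = field(default=None, repr=False)

    def featurize(self, record: ReactionRecord) -> np.ndarray:
        rec = record
        if self.target == DESCRIPTOR:
            rec = replace(rec, cocatalyst=coerce_cocatalyst_for_descriptor(rec.cocatalyst))
        return featurize_reaction(rec, self.config)


@dataclass(frozen=True)
class PredictionResult:
    mean: float
    std: float
    member_values: np.ndarray


@dataclass(frozen=True)
class CVReport:
    mae: float
    mse: float
    oof_predictions: np.ndarray  # per-row averaged out-of-fold predictions
    oof_counts: np.ndarray


def _target_value(record: ReactionRecord, target: str) -> float | None:
    return record.ddg if target == SELECTIVITY else record.descriptor


def prepare_training_records(records, target: str) -> list[ReactionRecord]:
    """Rows usable for training: target present and, for the descriptor
    model, non-cinchona catalysts with the coerced co-catalyst encoding."""
    out = []
    for r in records:
        if _target_value(r, target) is None:
            continue
        if target == DESCRIPTOR and is_cinchona(r.catalyst):
            continue
        out.append(r)
    return out


def _make_regressor(booster: str, seed: int, params: dict) -> xgb.XGBRegressor:
    base = dict(random_state=seed, n_jobs=1, tree_method="hist", verbosity=0)
    base.update(params)
    if booster == "rf":
        return xgb.XGBRFRegressor(**base)
    return xgb.XGBRegressor(**base)


def train_ensemble(
    records,
    target: str,
    config: FingerprintConfig | None = None,
    seed: int = 0,
    n_splits: int = 100,
    train_fraction: float = 0.9,
    booster: str = "gbtree",
    xgb_params: dict | None = None,
) -> SurrogateEnsemble:
    """Fit ``n_splits`` members on independent random train/test splits.

    Deterministic for a fixed seed.  Each member sees a fresh uniform
    permutation of the rows, the first ``train_fraction`` as training fold.
    """
    if target not in (SELECTIVITY, DESCRIPTOR):
        raise ValueError(f"unknown target {target!r}")
    if config is None:
        components = SELECTIVITY_COMPONENTS if target == SELECTIVITY else DESCRIPTOR_COMPONENTS
        config = FingerprintConfig(component_order=components)
    usable = prepare_training_records(records, target)
    if len(usable) < 20:
        raise ValueError(
            f"need >= 20 records with a {target} value, got {len(usable)}"
        )
    y = np.array([_target_value(r, target) for r in usable], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values in training rows")

    ens = SurrogateEnsemble(target, config, [], n_splits, train_fraction, seed, booster)
    X = np.stack([ens.featurize(r) for r in usable]).astype(np.float32)

    rng = np.random.default_rng(seed)
    n = len(usable)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    params = xgb_params or {}
    for s in range(n_splits):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        model = _make_regressor(booster, int(rng.integers(2**31 - 1)), params)
        model.fit(X[train_idx], y[train_idx])
        ens.members.append(EnsembleMember(model, train_idx, test_idx))
    ens.train_targets = y
    return ens


def predict(ensemble: SurrogateEnsemble, record: ReactionRecord) -> PredictionResult:
    """Mean and member spread of the ensemble's predictions for one record."""
    x = ensemble.featurize(record).astype(np.float32)[None, :]
    vals = np.array([m.model.predict(x)[0] for m in ensemble.members], dtype=float)
    return PredictionResult(float(vals.mean()), float(vals.std()), vals)


def predict_many(ensemble: SurrogateEnsemble, records) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction over records: (means, stds), each length n."""
    X = np.stack([ensemble.featurize(r) for r in records]).astype(np.float32)
    member_preds = np.stack([m.model.predict(X) for m in ensemble.members])
    return member_preds.mean(axis=0), member_preds.std(axis=0)


def out_of_fold_report(ensemble: SurrogateEnsemble, records) -> CVReport:
    """Averaged test-fold predictions and their MAE/MSE vs the targets.

    ``records`` must be the same rows (same order) the ensemble was trained
    on; each row is predicted by the members that held it out.
    """
    usable = prepare_training_records(records, ensemble.target)
    y = np.array([_target_value(r, ensemble.target) for r in usable], dtype=float)
    X = np.stack([ensemble.featurize(r) for r in usable]).astype(np.float32)
    sums = np.zeros(len(y))
    counts = np.zeros(len(y))
    for m in ensemble.members:
        preds = m.model.predict(X[m.test_idx])
        sums[m.test_idx] += preds
        counts[m.test_idx] += 1
    seen = counts > 0
    oof = np.full(len(y), np.nan)
    oof[seen] = sums[seen] / counts[seen]
    err = oof[seen] - y[seen]
    return CVReport(float(np.mean(np.abs(err))), float(np.mean(err**2)), oof, counts)


def evaluate_out_of_sample(ensemble: SurrogateEnsemble, held_out_records) -> CVReport:
    """MAE/MSE of ensemble-mean predictions on an external set."""
    held_out_records = list(held_out_records)
    if not held_out_records:
        raise ValueError("empty held-out set")
    y = np.array(
        [_target_value(r, ensemble.target) for r in held_out_records], dtype=float
    )
    if np.any([v is None or not np.isfinite(v) for v in y]):
        raise ValueError("held-out rows must carry the target value")
    means, _ = predict_many(ensemble, held_out_records)
    err = means - y
    return CVReport(
        float(np.mean(np.abs(err))), float(np.mean(err**2)), means, np.ones(len(y))
    )


def save_ensemble(ensemble: SurrogateEnsemble, directory) -> None:
    """Persist as a versioned directory of JSON member dumps plus metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "target": ensemble.target,
        "n_splits": ensemble.n_splits,
        "train_fraction": ensemble.train_fraction,
        "seed": ensemble.seed,
        "booster": ensemble.booster,
        "fingerprint": {
            "n_bits": ensemble.config.n_bits,
            "radius": ensemble.config.radius,
            "component_order": list(ensemble.config.component_order),
        },
        "members": [
            {
                "file": f"member_{i:03d}.json",
                "train_idx": m.train_idx.tolist(),
                "test_idx": m.test_idx.tolist(),
            }
            for i, m in enumerate(ensemble.members)
        ],
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    for i, m in enumerate(ensemble.members):
        booster = m.model.get_booster() if hasattr(m.model, "get_booster") else m.model.booster
        booster.save_model(str(d / f"member_{i:03d}.json"))


def load_ensemble(directory) -> SurrogateEnsemble:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    config = FingerprintConfig(
        n_bits=meta["fingerprint"]["n_bits"],
        radius=meta["fingerprint"]["radius"],
        component_order=tuple(meta["fingerprint"]["component_order"]),
    )
    members = []
    for entry in meta["members"]:
        booster = xgb.Booster()
        booster.load_model(str(d / entry["file"]))
        model = _LoadedBooster(booster)
        members.append(
            EnsembleMember(
                model,
                np.asarray(entry["train_idx"], dtype=int),
                np.asarray(entry["test_idx"], dtype=int),
            )
        )
    return SurrogateEnsemble(
        meta["target"], config, members, meta["n_splits"],
        meta["train_fraction"], meta["seed"], meta["booster"],
    )
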