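"""Boosted-tree log-cost regression and decile predictive-ratio calibration.

The risk model is a gradient-boosted tree ensemble trained on
log(observed_cost + c) with features (age, sex, k cluster-similarity
values).  Predictions are retransformed to dollars as exp(log-pred) - c and
then passed through a decile calibration table: beneficiaries are ranked by
predicted cost into 10 equal-count deciles and each decile's predictions
are scaled so its predictive ratio (mean predicted / mean observed) is
exactly 1 on the calibration set.  Decile calibration doubles as the
retransformation-bias correction, absorbing the smearing factor that plain
exponentiation of a log-scale prediction would miss.

A cost-scale baseline (such as the HCC-style scorer) is compared on the
log scale after a two-parameter OLS recalibration, log(obs + c) ~
a + b log(pred + c), fitted on a calibration split and applied
out-of-sample; this is monotone and rank-preserving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .claims_io import Cohort
from .embedding_clusters import ClusterModel, EmbeddingModel, cluster_feature_matrix

__all__ = [
    "DEFAULT_LOG_OFFSET",
    "DEFAULT_PAYMENT_FLOOR",
    "DEFAULT_HYPERPARAMS",
    "CalibrationTable",
    "RiskModelBundle",
    "build_design",
    "fit",
    "predict_log_cost",
    "calibrate_deciles",
    "predict_cost",
    "fit_log_recalibration",
    "apply_log_recalibration",
]

#: Offset c in log(cost + c); keeps zero-cost beneficiaries finite.
DEFAULT_LOG_OFFSET = 1.0

#: Lower bound on cost-scale predictions (USD), applied before calibration.
DEFAULT_PAYMENT_FLOOR = 1.0

#: Conventional boosting settings; tuned via the validation split.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 500,
    "max_depth": 6,
    "learning_rate": 0.05,
    "subsample": 0.8,
    "early_stopping_rounds": 20,
}


def build_design(
    cohort: Cohort,
    emb: EmbeddingModel,
    clusters: ClusterModel,
    offset: float = DEFAULT_LOG_OFFSET,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (age, sex, k cluster features) and log-cost target.

    One row per beneficiary; column 0 is age in years, column 1 a female
    indicator, columns 2..k+1 the cluster-similarity features.  The target
    is natural log(observed_cost + offset).
    """
    cost = cohort.table["observed_cost"].to_numpy(dtype=float)
    if (cost < 0).any():
        raise ValueError("observed_cost must be >= 0")
    features = cluster_feature_matrix(cohort, emb, clusters)
    age = cohort.table["age"].to_numpy(dtype=float)
    female = (cohort.table["sex"] == "F").to_numpy(dtype=float)
    x = np.column_stack([age, female, features])
    y = np.log(cost + offset)
    return x, y


@dataclass(frozen=True)
class CalibrationTable:
    """Decile boundaries on predicted cost plus per-decile scale factors.

    ``boundaries`` hold the largest predicted value in each of the first 9
    deciles of the fitting set; a prediction p falls in decile
    searchsorted(boundaries, p, side="left").  Factors multiply cost-scale
    predictions so each decile's predictive ratio is 1 on the set the table
    was fitted on.
    """

    boundaries: np.ndarray  # (9,)
    factors: np.ndarray  # (10,)

    def __post_init__(self) -> None:
        if len(self.factors) != len(self.boundaries) + 1:
            raise ValueError("need one factor per decile (len(boundaries)+1)")
        if np.any(np.diff(self.boundaries) < 0):
            raise ValueError("boundaries must be nondecreasing")
        if np.any(self.factors <= 0):
            raise ValueError("factors must be positive")

    def decile_of(self, predicted: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.boundaries, np.asarray(predicted), side="left")

    def apply(self, predicted: np.ndarray) -> np.ndarray:
        predicted = np.asarray(predicted, dtype=float)
        return predicted * self.factors[self.decile_of(predicted)]


def calibrate_deciles(
    predicted_cost: np.ndarray, observed_cost: np.ndarray
) -> CalibrationTable:
    """Fit per-decile factors making the predictive ratio 1 in each decile.

    Beneficiaries are ranked by predicted cost (stable sort, so ties break
    by input order) into 10 equal-count deciles; each decile's factor is
    mean(observed) / mean(predicted).
    """
    predicted_cost = np.asarray(predicted_cost, dtype=float)
    observed_cost = np.asarray(observed_cost, dtype=float)
    n = len(predicted_cost)
    if len(observed_cost) != n:
        raise ValueError("predicted and observed lengths differ")
    if n < 10:
        raise ValueError("need at least 10 pairs to form deciles")
    order = np.argsort(predicted_cost, kind="stable")
    groups = np.array_split(order, 10)
    factors = np.empty(10)
    boundaries = np.empty(9)
    for d, g in enumerate(groups):
        mean_pred = predicted_cost[g].mean()
        if mean_pred == 0:
            raise ValueError(f"decile {d} has mean predicted cost 0")
        factors[d] = observed_cost[g].mean() / mean_pred
        if d < 9:
            boundaries[d] = predicted_cost[g].max()
    return CalibrationTable(boundaries=boundaries, factors=factors)


@dataclass
class RiskModelBundle:
    """A fitted risk model plus everything needed to reproduce predictions."""

    booster: xgb.XGBRegressor
    emb: EmbeddingModel
    clusters: ClusterModel
    offset: float = DEFAULT_LOG_OFFSET
    payment_floor: float = DEFAULT_PAYMENT_FLOOR
    calibration: CalibrationTable | None = None
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    best_iteration: int | None = None


def fit(
    train_cohort: Cohort,
    validation_cohort: Cohort,
    emb: EmbeddingModel,
    clusters: ClusterModel,
    hyperparams: Mapping[str, object] | None = None,
    offset: float = DEFAULT_LOG_OFFSET,
    seed: int = 0,
) -> RiskModelBundle:
    """Train the boosted ensemble on log cost with validation early stopping."""
    if len(train_cohort) == 0:
        raise ValueError("training cohort is empty")
    overlap = set(train_cohort.table["id"]) & set(validation_cohort.table["id"])
    if overlap:
        raise ValueError(f"train/validation cohorts overlap: {sorted(overlap)[:5]}")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    x_train, y_train = build_design(train_cohort, emb, clusters, offset)
    x_val, y_val = build_design(validation_cohort, emb, clusters, offset)
    model = xgb.XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **hp,
    )
    model.fit(x_train, y_train, eval_set=[(x_val, y_val)], verbose=False)
    best_it = getattr(model, "best_iteration", None)
    return RiskModelBundle(
        booster=model,
        emb=emb,
        clusters=clusters,
        offset=offset,
        hyperparams=hp,
        best_iteration=best_it,
    )


def predict_log_cost(bundle: RiskModelBundle, cohort: Cohort) -> np.ndarray:
    """Predicted log(cost + offset) per beneficiary (finite by construction)."""
    x, _ = build_design(cohort, bundle.emb, bundle.clusters, bundle.offset)
    pred = bundle.booster.predict(x)
    return np.asarray(pred, dtype=float)


def predict_cost(bundle: RiskModelBundle, cohort: Cohort) -> np.ndarray:
    """Dollar-scale predictions: exp(log-pred) - c, floored, decile-calibrated."""
    log_pred = predict_log_cost(bundle, cohort)
    raw = np.maximum(np.exp(log_pred) - bundle.offset, bundle.payment_floor)
    if bundle.calibration is not None:
        return bundle.calibration.apply(raw)
    return raw


def fit_log_recalibration(
    predicted_cost: np.ndarray,
    observed_cost: np.ndarray,
    offset: float = DEFAULT_LOG_OFFSET,
) -> tuple[float, float]:
    """OLS of log(obs + c) on log(pred + c): returns (intercept, slope).

    Used to place cost-scale baselines on the log scale for fit comparison;
    fit on a calibration split, apply out-of-sample.
    """
    x = np.log(np.asarray(predicted_cost, dtype=float) + offset)
    y = np.log(np.asarray(observed_cost, dtype=float) + offset)
    if np.var(x) == 0:
        return float(y.mean()), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def apply_log_recalibration(
    coeffs: tuple[float, float],
    predicted_cost: np.ndarray,
    offset: float = DEFAULT_LOG_OFFSET,
) -> np.ndarray:
    """Recalibrated log-scale predictions a + b*log(pred + c)."""
    intercept, slope = coeffs
    return intercept + slope * np.log(np.asarray(predicted_cost, dtype=float) + offset)


class _BoosterPredictor:
    """Raw-Booster adapter honoring the early-stopped iteration count."""

    def __init__(self, booster: xgb.Booster, best_iteration: int | None = None):
        self._booster = booster
        self.best_iteration = best_iteration

    def predict(self, x: np.ndarray) -> np.ndarray:
        dm = xgb.DMatrix(np.asarray(x))
        if self.best_iteration is not None:
            return self._booster.predict(dm, iteration_range=(0, self.best_iteration + 1))
        return self._booster.predict(dm)

    def get_booster(self) -> xgb.Booster:
        return self._booster


def save_bundle(bundle: RiskModelBundle, path: str | Path) -> None:
    """Serialize a bundle to a directory (JSON model dump + CSV + npz)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    raw = bundle.booster.get_booster()
    raw.save_model(str(path / "model.json"))
    np.savez(
        path / "embedding.npz",
        vectors=bundle.emb.vectors,
        centers=bundle.clusters.centers,
        assignments=bundle.clusters.assignments,
    )
    pd.DataFrame({"code": bundle.emb.vocab}).to_csv(path / "vocab.csv", index=False)
    if bundle.calibration is not None:
        pd.DataFrame(
            {
                "decile": np.arange(10),
                "upper_boundary": np.append(bundle.calibration.boundaries, np.inf),
                "factor": bundle.calibration.factors,
            }
        ).to_csv(path / "calibration.csv", index=False)
    meta = {
        "offset": bundle.offset,
        "payment_floor": bundle.payment_floor,
        "hyperparams": {k: v for k, v in bundle.hyperparams.items()},
        "best_iteration": bundle.best_iteration,
        "d": bundle.emb.d,
        "cluster_seed": int(bundle.clusters.seed),
        "cluster_inertia": bundle.clusters.inertia,
        "embedding_meta": dict(bundle.emb.meta),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_bundle(path: str | Path) -> RiskModelBundle:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    raw = xgb.Booster()
    raw.load_model(str(path / "model.json"))
    booster = _BoosterPredictor(raw, meta.get("best_iteration"))
    arrays = np.load(path / "embedding.npz")
    vocab = tuple(pd.read_csv(path / "vocab.csv", dtype=str)["code"])
    emb = EmbeddingModel(
        vocab=vocab,
        vectors=arrays["vectors"],
        d=int(meta["d"]),
        meta=meta.get("embedding_meta", {}),
    )
    clusters = ClusterModel(
        centers=arrays["centers"],
        assignments=arrays["assignments"],
        inertia=float(meta["cluster_inertia"]),
        seed=int(meta["cluster_seed"]),
    )
    calibration = None
    calib_path = path / "calibration.csv"
    if calib_path.exists():
        calib = pd.read_csv(calib_path)
        calibration = CalibrationTable(
            boundaries=calib["upper_boundary"].to_numpy()[:9],
            factors=calib["factor"].to_numpy(),
        )
    return RiskModelBundle(
        booster=booster,
        emb=emb,
        clusters=clusters,
        offset=float(meta["offset"]),
        payment_floor=float(meta["payment_floor"]),
        calibration=calibration,
        hyperparams=meta.get("hyperparams", {}),
        best_iteration=meta.get("best_iteration"),
    )
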