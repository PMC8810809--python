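"""Model/Results objects for the shallow dense glucose regressor.

`GlucoseSDNN` is constructed from a cohort DataFrame (3 NIR readouts + 6
medical features against reference plasma glucose); `fit` returns an
`SDNNResults` carrying the trained network, the feature scaler, training
diagnostics and evaluation helpers.  `cross_validate` runs stratified k-fold
cross-validation (default ten folds, stratified on the 126 mg/dL diabetes
label, feature scaling refit inside each fold so no information leaks from the
validation fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network
from .cohort import DM_THRESHOLD, MODEL_INPUT_FIELDS
from .evaluation import (
    ConfusionMatrix,
    EvaluationReport,
    MetricSet,
    confusion_metrics,
    evaluate_predictions,
)
from .network import FeatureScaler, NetworkParameters, TrainingConfig

__all__ = [
    "GlucoseSDNN",
    "SDNNResults",
    "FoldResult",
    "CrossValidationResult",
    "classify",
    "stratified_kfold",
]


def classify(predicted_glucose, threshold: float = DM_THRESHOLD):
    """Binary diabetes label from predicted glucose: 1 iff >= threshold.

    The boundary is inclusive, following the fasting-glucose diagnostic
    criterion of 126 mg/dL or higher.
    """
    g = np.asarray(predicted_glucose, dtype=float)
    if np.any(g < 0):
        raise ValueError("predicted glucose must be >= 0")
    out = (g >= threshold).astype(int)
    return int(out) if np.isscalar(predicted_glucose) else out


def stratified_kfold(labels, k: int, rng) -> list[np.ndarray]:
    """Index partition into k folds, stratified on a binary label.

    Within each class the (shuffled) indices are dealt round-robin, so every
    fold's class ratio is within one sample of the global ratio.  Falls back
    to unstratified folds with a warning if only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"dataset of size {n} cannot be split into {k} folds")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    classes = np.unique(labels)
    if classes.size < 2:
        warnings.warn("only one class present; falling back to unstratified folds")
    folds = [[] for _ in range(k)]
    offset = 0
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            folds[(offset + j) % k].append(int(i))
        offset += idx.size  # keep fold sizes balanced across classes
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


@dataclass(frozen=True)
class FoldResult:
    """Validation outcome of one cross-validation fold."""

    fold_index: int
    confusion: ConfusionMatrix
    metrics: MetricSet
    errors: np.ndarray  # per-sample predicted - reference, mg/dL
    val_indices: np.ndarray


@dataclass(frozen=True)
class CrossValidationResult:
    folds: list
    pooled_confusion: ConfusionMatrix
    pooled_metrics: MetricSet
    pooled_predictions: pd.DataFrame  # index, glucose_ref, glucose_pred

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            rows.append(
                {
                    "fold": f.fold_index,
                    "n_val": int(f.val_indices.size),
                    "tp": f.confusion.tp,
                    "fp": f.confusion.fp,
                    "fn": f.confusion.fn,
                    "tn": f.confusion.tn,
                    **{k: v for k, v in f.metrics.as_dict().items()},
                    "mae": float(np.mean(np.abs(f.errors))),
                }
            )
        return pd.DataFrame(rows)


class GlucoseSDNN:
    """Shallow dense neural-network regressor of plasma glucose.

    Parameters
    ----------
    exog : (n, p) array of model inputs (NIR readouts + medical features).
    endog : (n,) reference plasma glucose in mg/dL.
    feature_names : column names of ``exog``; defaults to the canonical nine
        input fields.
    """

    def __init__(self, endog, exog, feature_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have equal length")
        if feature_names is None:
            if self.exog.shape[1] != len(MODEL_INPUT_FIELDS):
                raise ValueError(
                    "feature_names required when exog does not have the canonical 9 columns"
                )
            feature_names = list(MODEL_INPUT_FIELDS)
        if len(feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length must match exog width")
        self.feature_names = list(feature_names)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, features=None, target: str = "glucose_ref"
    ) -> "GlucoseSDNN":
        """Build the model from a cohort DataFrame in the canonical schema."""
        features = list(features) if features is not None else list(MODEL_INPUT_FIELDS)
        missing = [c for c in features + [target] if c not in df.columns]
        if missing:
            raise ValueError(f"dataframe missing columns: {missing}")
        return cls(df[target].to_numpy(), df[features].to_numpy(), feature_names=features)

    def fit(self, config: TrainingConfig | None = None) -> "SDNNResults":
        """Train by mini-batch gradient descent; deterministic given the seed."""
        config = config or TrainingConfig()
        params, scaler, history = network.train(self.exog, self.endog, config)
        return SDNNResults(self, params, scaler, config, history)

    def cross_validate(
        self, k: int = 10, config: TrainingConfig | None = None, threshold: float = DM_THRESHOLD
    ) -> CrossValidationResult:
        """Stratified k-fold cross-validation with per-fold refitting.

        Feature scaling and the network are refit on each training split;
        every sample appears in exactly one validation fold, and the pooled
        confusion counts therefore sum to the dataset size.
        """
        config = config or TrainingConfig()
        labels = (self.endog >= threshold).astype(int)
        folds_idx = stratified_kfold(labels, k, np.random.default_rng(config.seed))
        all_idx = np.arange(self.endog.size)
        fold_results = []
        pooled_rows = []
        pooled_cm = ConfusionMatrix(0, 0, 0, 0)
        for j, val_idx in enumerate(folds_idx, start=1):
            tr_mask = np.ones(self.endog.size, dtype=bool)
            tr_mask[val_idx] = False
            tr_idx = all_idx[tr_mask]
            fold_cfg = config.replace(seed=config.seed + j)
            params, scaler, _ = network.train(
                self.exog[tr_idx], self.endog[tr_idx], fold_cfg
            )
            pred = (
                network.forward(scaler.transform(self.exog[val_idx]), params)
                * fold_cfg.target_scaling
            )
            cm = ConfusionMatrix.from_labels(labels[val_idx], classify(pred, threshold))
            pooled_cm = pooled_cm + cm
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small folds may lack a class
                metrics = confusion_metrics(cm)
            fold_results.append(
                FoldResult(
                    fold_index=j,
                    confusion=cm,
                    metrics=metrics,
                    errors=pred - self.endog[val_idx],
                    val_indices=val_idx,
                )
            )
            pooled_rows.append(
                pd.DataFrame(
                    {"index": val_idx, "glucose_ref": self.endog[val_idx], "glucose_pred": pred}
                )
            )
        pooled = pd.concat(pooled_rows, ignore_index=True).sort_values("index", ignore_index=True)
        return CrossValidationResult(
            folds=fold_results,
            pooled_confusion=pooled_cm,
            pooled_metrics=confusion_metrics(pooled_cm),
            pooled_predictions=pooled,
        )


class SDNNResults:
    """Fitted shallow dense network with its scaler and training history."""

    def __init__(self, model, params: NetworkParameters, scaler: FeatureScaler,
                 config: TrainingConfig, history: dict):
        self.model = model
        self.params = params
        self.scaler = scaler
        self.config = config
        self.history = history

    # -- prediction --------------------------------------------------------
    def _exog_from(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            missing = [c for c in self.model.feature_names if c not in data.columns]
            if missing:
                raise ValueError(f"dataframe missing model features: {missing}")
            return data[self.model.feature_names].to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(data, dtype=float))

    def predict(self, data=None) -> np.ndarray:
        """Predicted glucose in mg/dL for a DataFrame or feature matrix."""
        X = self.model.exog if data is None else self._exog_from(data)
        return network.forward(self.scaler.transform(X), self.params) * self.config.target_scaling

    def classify(self, data=None, threshold: float = DM_THRESHOLD) -> np.ndarray:
        """Thresholded diabetes label from the regression output."""
        return classify(self.predict(data), threshold)

    def evaluate(
        self, data: pd.DataFrame, threshold: float = DM_THRESHOLD, ba_mode: str = "percent"
    ) -> EvaluationReport:
        """Full clinical evaluation against the ``glucose_ref`` column."""
        if "glucose_ref" not in data.columns:
            raise ValueError("evaluation data must carry a glucose_ref column")
        pred = self.predict(data)
        return evaluate_predictions(
            data["glucose_ref"].to_numpy(dtype=float), pred, threshold=threshold, ba_mode=ba_mode
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        sizes = " -> ".join(str(s) for s in self.params.layer_sizes)
        h = self.history
        in_sample = self.evaluate(
            pd.DataFrame(self.model.exog, columns=self.model.feature_names).assign(
                glucose_ref=self.model.endog
            )
        )
        lines = [
            "Shallow dense neural network glucose regression",
            "=" * 48,
            f"architecture     {sizes} (sigmoid hidden, {self.params.output_activation} output)",
            f"n observations   {self.model.endog.size}",
            f"features         {', '.join(self.model.feature_names)}",
            f"target scaling   glucose / {self.config.target_scaling:g}",
            f"optimizer        mini-batch GD, lr={self.config.learning_rate:g}, "
            f"batch={self.config.batch_size}, momentum={self.config.momentum:g}",
            f"epochs run       {int(h['epoch'][-1]) + 1} (of max {self.config.epochs})",
            f"final train MSE  {h['train_loss'][-1]:.3e} (scaled target)",
            f"final val MSE    {h['val_loss'][-1]:.3e}",
            "-" * 48,
            "in-sample " + in_sample.summary(),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        network.save_params(path, self.params, self.scaler, self.config,
                            self.model.feature_names)

    @classmethod
    def load(cls, path) -> "SDNNResults":
        params, scaler, target_scaling, names = network.load_params(path)
        config = TrainingConfig(target_scaling=target_scaling,
                                output_activation=params.output_activation)
        n_in = params.layer_sizes[0]
        dummy = GlucoseSDNN(
            np.zeros(1), np.zeros((1, n_in)),
            feature_names=names or [f"x{i}" for i in range(n_in)],
        )
        history = {"epoch": np.array([0]), "train_loss": np.array([np.nan]),
                   "val_loss": np.array([np.nan])}
        return cls(dummy, params, scaler, config, history)
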