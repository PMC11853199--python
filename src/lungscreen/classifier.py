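"""Four-class feed-forward screening network.

Architecture: input layer sized to the selected features, one hidden layer
with rectified-linear activation, softmax output over the four respiratory
classes, categorical cross-entropy loss. Regularization follows standard
practice for small tabular networks: inverted dropout on the hidden layer,
an L2 weight penalty added to the loss, and early stopping on a held-out
validation slice with best-weight restoration. Optimization is Adam on
shuffled mini-batches; every source of randomness (initialization, batch
order, dropout masks, validation split) flows from the config seed, so a
fixed (data, config, seed) triple reproduces the trained weights exactly on
a given platform.

Features are standardized (z-scored) with statistics estimated on the
training split; the statistics travel with the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from lungscreen.audio_io import CLASS_ORDER
from lungscreen.errors import ContractError, TrainingFailureError
from lungscreen.features import FEATURE_NAMES

_DEFAULT_CLASS_ORDER = tuple(c.value for c in CLASS_ORDER)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the screening network.

    ``early_stopping_patience=None`` disables validation monitoring and
    trains for the full ``max_epochs``.
    """

    n_hidden: int = 250
    max_epochs: int = 1000
    dropout_rate: float = 0.3
    l2_penalty: float = 1e-4
    early_stopping_patience: Optional[int] = 50
    validation_fraction: float = 0.1
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ContractError("n_hidden must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ContractError("dropout_rate must be in [0, 1)")
        if self.l2_penalty < 0:
            raise ContractError("l2_penalty must be non-negative")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ContractError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be positive")


@dataclass
class TrainedModel:
    """Weights plus everything needed to apply them to new feature rows."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    feature_names: tuple[str, ...]
    class_order: tuple[str, ...]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config: ModelConfig
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _resolve_class_order(labels: Sequence[str]) -> tuple[str, ...]:
    present = set(labels)
    if present <= set(_DEFAULT_CLASS_ORDER):
        return _DEFAULT_CLASS_ORDER
    return tuple(sorted(present))


def split_dataset(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a labeled feature table (default 80:20)."""
    if "label" not in table.columns:
        raise ContractError("table needs a 'label' column")
    counts = table["label"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ContractError(f"every class needs >= 2 rows to stratify; too few: {small}")
    train_tbl, test_tbl = train_test_split(
        table,
        test_size=test_fraction,
        random_state=seed,
        stratify=table["label"],
        shuffle=True,
    )
    return train_tbl.reset_index(drop=True), test_tbl.reset_index(drop=True)


def balance_classes(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random oversampling (with replacement) of minority classes.

    Every class is brought up to the majority count. Meant for the training
    split only; an already balanced table is returned with its row multiset
    unchanged.
    """
    if "label" not in table.columns:
        raise ContractError("table needs a 'label' column")
    counts = table["label"].value_counts()
    if counts.empty or (counts < 1).any():
        raise ContractError("every class must have at least one row")
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    parts = []
    for label, group in table.groupby("label", sort=True):
        parts.append(group)
        deficit = target - len(group)
        if deficit > 0:
            extra_idx = rng.integers(0, len(group), size=deficit)
            parts.append(group.iloc[extra_idx])
    return pd.concat(parts).reset_index(drop=True)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(x, w1, b1, w2, b2):
    hidden = np.maximum(x @ w1 + b1, 0.0)
    return hidden, _softmax(hidden @ w2 + b2)


def _loss(probs, y_onehot, w1, w2, l2):
    ce = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
    return ce + l2 * (np.sum(w1**2) + np.sum(w2**2))


def train(
    table: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Fit the network on a labeled feature table.

    ``feature_names`` selects and orders the input columns (defaults to the
    full 13-feature set). A ``validation_fraction`` stratified slice of the
    rows is held out for early stopping when patience is set; the weights
    achieving the lowest validation loss are restored.
    """
    if feature_names is None:
        feature_names = [f for f in FEATURE_NAMES if f in table.columns]
    feature_names = tuple(feature_names)
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ContractError(f"table missing feature columns: {missing}")
    if "label" not in table.columns or len(table) == 0:
        raise ContractError("non-empty labeled table required")
    labels = table["label"].astype(str).to_numpy()
    class_order = _resolve_class_order(labels)
    if len(set(labels)) < 2:
        raise ContractError("training requires at least 2 classes")

    x = table[list(feature_names)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ContractError("feature values must be finite")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0.0] = 1.0
    x = (x - mean) / scale
    class_index = {c: i for i, c in enumerate(class_order)}
    y = np.array([class_index[l] for l in labels])
    n_classes = len(class_order)
    y_onehot = np.eye(n_classes)[y]

    rng = np.random.default_rng(config.seed)

    # validation slice for early stopping
    if config.early_stopping_patience is not None:
        n_val = max(1, int(round(config.validation_fraction * len(x))))
        perm = rng.permutation(len(x))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ContractError("validation fraction leaves no training rows")
    else:
        train_idx = rng.permutation(len(x))
        val_idx = np.array([], dtype=int)
    x_tr, y_tr = x[train_idx], y_onehot[train_idx]
    x_val, y_val = x[val_idx], y_onehot[val_idx]

    d, h = len(feature_names), config.n_hidden
    w1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, n_classes))
    b2 = np.zeros(n_classes)
    params = [w1, b1, w2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_params = [p.copy() for p in params]
    patience_left = config.early_stopping_patience
    history = {"train_loss": [], "train_accuracy": [], "val_loss": []}
    keep = 1.0 - config.dropout_rate

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(x_tr), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            w1, b1, w2, b2 = params
            hidden = np.maximum(xb @ w1 + b1, 0.0)
            if config.dropout_rate > 0.0:
                mask = (rng.random(hidden.shape) < keep) / keep
                hidden_drop = hidden * mask
            else:
                hidden_drop = hidden
            probs = _softmax(hidden_drop @ w2 + b2)
            n_b = len(xb)
            delta_out = (probs - yb) / n_b
            grad_w2 = hidden_drop.T @ delta_out + 2 * config.l2_penalty * w2
            grad_b2 = delta_out.sum(axis=0)
            delta_hidden = delta_out @ w2.T
            if config.dropout_rate > 0.0:
                delta_hidden = delta_hidden * mask
            delta_hidden = delta_hidden * (hidden > 0)
            grad_w1 = xb.T @ delta_hidden + 2 * config.l2_penalty * w1
            grad_b1 = delta_hidden.sum(axis=0)
            step += 1
            for i, grad in enumerate([grad_w1, grad_b1, grad_w2, grad_b2]):
                m_t[i] = beta1 * m_t[i] + (1 - beta1) * grad
                v_t[i] = beta2 * v_t[i] + (1 - beta2) * grad**2
                m_hat = m_t[i] / (1 - beta1**step)
                v_hat = v_t[i] / (1 - beta2**step)
                params[i] = params[i] - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            w1, b1, w2, b2 = params

        _, probs_tr = _forward(x_tr, *params)
        train_loss = _loss(probs_tr, y_tr, params[0], params[2], config.l2_penalty)
        if not np.isfinite(train_loss):
            raise TrainingFailureError(f"loss diverged at epoch {epoch}")
        history["train_loss"].append(float(train_loss))
        history["train_accuracy"].append(
            float(np.mean(probs_tr.argmax(axis=1) == y_tr.argmax(axis=1)))
        )

        if config.early_stopping_patience is not None:
            _, probs_val = _forward(x_val, *params)
            val_loss = _loss(probs_val, y_val, params[0], params[2], config.l2_penalty)
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if config.early_stopping_patience is not None:
        params = best_params

    return TrainedModel(
        w1=params[0],
        b1=params[1],
        w2=params[2],
        b2=params[3],
        feature_names=feature_names,
        class_order=class_order,
        feature_mean=mean,
        feature_scale=scale,
        config=config,
        history=history,
    )


def predict_proba(
    model: TrainedModel, features: Union[np.ndarray, pd.DataFrame, Sequence[float]]
) -> np.ndarray:
    """Class probabilities for one feature row or a batch.

    A DataFrame is reindexed to the model's feature order; a bare array must
    already match it. Returns shape (n, #classes) for 2-D input, (#classes,)
    for a single row.
    """
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in features.columns]
        if missing:
            raise ContractError(f"missing feature columns: {missing}")
        x = features[list(model.feature_names)].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ContractError(
            f"feature width {x.shape[1]} != model input width {model.n_features}"
        )
    x = (x - model.feature_mean) / model.feature_scale
    _, probs = _forward(x, model.w1, model.b1, model.w2, model.b2)
    return probs[0] if single else probs


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predicted class labels (argmax of the softmax probabilities)."""
    probs = np.atleast_2d(predict_proba(model, features))
    return np.asarray([model.class_order[i] for i in probs.argmax(axis=1)])


def evaluate_accuracy(model: TrainedModel, table: pd.DataFrame) -> float:
    """Fraction of rows whose predicted label matches the ``label`` column."""
    predicted = predict(model, table)
    return float(np.mean(predicted == table["label"].astype(str).to_numpy()))


@dataclass(frozen=True)
class SweepResult:
    n_hidden: int
    train_accuracy: float
    test_accuracy: float


def hidden_node_sweep(
    table: pd.DataFrame,
    node_counts: Sequence[int],
    base_config: ModelConfig = ModelConfig(),
    feature_names: Optional[Sequence[str]] = None,
    test_fraction: float = 0.2,
    split_seed: int = 0,
    accuracy_tolerance: float = 0.01,
) -> tuple[list[SweepResult], int]:
    """Train/test accuracy versus hidden-layer width, on one shared split.

    Returns one result row per count plus the selected count: among counts
    whose test accuracy is within ``accuracy_tolerance`` of the best, the
    one with the smallest train-test gap (ties toward fewer nodes).
    """
    if len(node_counts) == 0:
        raise ContractError("node_counts must be non-empty")
    train_tbl, test_tbl = split_dataset(table, test_fraction=test_fraction, seed=split_seed)
    results = []
    for n in node_counts:
        cfg = ModelConfig(**{**asdict(base_config), "n_hidden": int(n)})
        model = train(train_tbl, cfg, feature_names=feature_names)
        results.append(
            SweepResult(
                n_hidden=int(n),
                train_accuracy=evaluate_accuracy(model, train_tbl),
                test_accuracy=evaluate_accuracy(model, test_tbl),
            )
        )
    best_acc = max(r.test_accuracy for r in results)
    candidates = [r for r in results if r.test_accuracy >= best_acc - accuracy_tolerance]
    selected = min(
        candidates,
        key=lambda r: (abs(r.train_accuracy - r.test_accuracy), r.n_hidden),
    ).n_hidden
    return results, selected


_SCHEMA_VERSION = 1


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Serialize a trained model to a single JSON archive."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "feature_names": list(model.feature_names),
        "class_order": list(model.class_order),
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "config": asdict(model.config),
        "weights": {
            "w1": model.w1.tolist(),
            "b1": model.b1.tolist(),
            "w2": model.w2.tolist(),
            "b2": model.b2.tolist(),
        },
        "history": model.history,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: Union[str, Path]) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ContractError(
            f"unsupported model schema version {payload.get('schema_version')!r}"
        )
    w = payload["weights"]
    return TrainedModel(
        w1=np.asarray(w["w1"]),
        b1=np.asarray(w["b1"]),
        w2=np.asarray(w["w2"]),
        b2=np.asarray(w["b2"]),
        feature_names=tuple(payload["feature_names"]),
        class_order=tuple(payload["class_order"]),
        feature_mean=np.asarray(payload["feature_mean"]),
        feature_scale=np.asarray(payload["feature_scale"]),
        config=ModelConfig(**payload["config"]),
        history=payload.get("history", {}),
    )
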