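"""Species assignment: feedforward network, stratified splitting, grid search.

The classifier is a multi-layer feedforward network trained by minibatch
stochastic gradient descent with backpropagation on a multinomial
cross-entropy objective.  Sparsity (l1) and weight decay (l2) regularization
are applied as proximal/decoupled updates, which keeps training stable in
the penalty-dominated limit.  Inputs are standardized per feature using
training-set statistics stored with the model.  Hyperparameters are explored
by a seeded random walk over a parameter grid bounded by a model-count and
an optional runtime stopping criterion; the winning model maximizes
validation accuracy with ties broken by lower validation RMSE, then by
earlier evaluation order.
"""

from __future__ import annotations

import itertools
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["SplitSpec", "NetConfig", "GridSearchSpec", "TrainedModel",
           "Prediction", "split_corpus", "train_fann", "grid_search",
           "predict", "default_search_grid", "save_model", "load_model"]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    stratify: bool = True
    group_by_specimen: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")


@dataclass(frozen=True)
class NetConfig:
    hidden_layers: tuple[int, ...] = (64, 32)
    activation: str = "relu"  # "relu" | "tanh"
    epochs: int = 50
    learning_rate: float = 0.05
    l1: float = 0.0
    l2: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class GridSearchSpec:
    params: dict[str, list] = field(default_factory=dict)
    max_models: int = 301
    max_runtime_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_models < 1:
            raise ValueError("max_models must be at least 1")


def default_search_grid() -> dict[str, list]:
    """The shipped hyperparameter space (432 combinations)."""
    return {
        "hidden_layers": [(32,), (64,), (64, 32), (128, 64)],
        "activation": ["relu", "tanh"],
        "learning_rate": [0.01, 0.05, 0.1],
        "l1": [0.0, 1e-5, 1e-4],
        "l2": [0.0, 1e-4, 1e-3],
        "epochs": [25, 50],
    }


@dataclass
class TrainedModel:
    config: NetConfig
    classes: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    train_accuracy: float
    validation_accuracy: float
    train_rmse: float
    validation_rmse: float
    history: pd.DataFrame


@dataclass
class Prediction:
    run_id: str
    predicted: str
    scores: np.ndarray
    classes: list[str]

    @property
    def margin(self) -> float:
        top2 = np.sort(self.scores)[-2:]
        return float(top2[1] - top2[0])


def split_corpus(matrix: FeatureMatrix, spec: SplitSpec | None = None,
                 ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified (optionally specimen-grouped) train/validation split.

    Exact-count per-stratum rounding keeps every species within one row of
    the global fraction; a single-row stratum cannot be split and goes to
    the training side with a warning.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray([l if l is not None else "" for l in matrix.labels])
    n = len(labels)
    train_idx: list[int] = []
    val_idx: list[int] = []
    groups = sorted(set(labels)) if spec.stratify else ["all"]
    for g in groups:
        idx = np.nonzero(labels == g)[0] if spec.stratify else np.arange(n)
        if spec.group_by_specimen:
            specimens = sorted(set(matrix.specimen_ids[i] for i in idx))
            perm = rng.permutation(len(specimens))
            n_train = min(max(int(round(spec.train_fraction * len(specimens))), 1),
                          max(len(specimens) - 1, 1))
            chosen = {specimens[p] for p in perm[:n_train]}
            for i in idx:
                (train_idx if matrix.specimen_ids[i] in chosen else val_idx).append(i)
        else:
            if len(idx) == 1:
                warnings.warn(f"stratum {g!r} has a single row; assigned to train")
                train_idx.extend(idx)
                continue
            perm = rng.permutation(len(idx))
            n_train = min(max(int(round(spec.train_fraction * len(idx))), 1),
                          len(idx) - 1)
            train_idx.extend(idx[perm[:n_train]])
            val_idx.extend(idx[perm[n_train:]])
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(val_idx))


# ---------------------------------------------------------------------------
# network internals

def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(a: np.ndarray, kind: str) -> np.ndarray:
    return (a > 0).astype(float) if kind == "relu" else 1.0 - a * a


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(x: np.ndarray, weights, biases, activation: str):
    acts = [x]
    for w, b in zip(weights[:-1], biases[:-1]):
        acts.append(_activate(acts[-1] @ w + b, activation))
    acts.append(_softmax(acts[-1] @ weights[-1] + biases[-1]))
    return acts


def _metrics(p: np.ndarray, y_onehot: np.ndarray) -> tuple[float, float]:
    acc = 100.0 * float((p.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
    rmse = float(np.sqrt(np.mean((p - y_onehot) ** 2)))
    return acc, rmse


def train_fann(config: NetConfig, train: FeatureMatrix, validation: FeatureMatrix,
               classes: list[str] | None = None) -> TrainedModel:
    """Train the network by minibatch SGD with backpropagation.

    ``classes`` fixes the output layer (e.g. the full panel); by default the
    sorted training labels are used.  Per-epoch accuracy and RMSE (one-hot
    targets vs softmax scores) on both sides are logged in the history.
    """
    if train.n_features != validation.n_features:
        raise ValueError("train/validation feature widths differ")
    labels = [l for l in train.labels]
    if classes is None:
        classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    class_index = {c: i for i, c in enumerate(classes)}

    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0)
    sigma = np.where(sigma < 1e-8, 1.0, sigma)
    x_tr = (train.values - mu) / sigma
    x_va = (validation.values - mu) / sigma
    y_tr = np.zeros((len(labels), len(classes)))
    y_tr[np.arange(len(labels)), [class_index[l] for l in labels]] = 1.0
    y_va = np.zeros((len(validation.labels), len(classes)))
    y_va[np.arange(len(validation.labels)),
         [class_index[l] for l in validation.labels]] = 1.0

    rng = np.random.default_rng(config.seed)
    sizes = [train.n_features, *config.hidden_layers, len(classes)]
    weights = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [np.zeros(s) for s in sizes[1:]]

    lr = config.learning_rate
    decay = max(0.0, 1.0 - lr * config.l2)
    shrink = lr * config.l1
    history = []
    n = len(x_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            acts = _forward(x_tr[batch], weights, biases, config.activation)
            delta = (acts[-1] - y_tr[batch]) / len(batch)
            for layer in range(len(weights) - 1, -1, -1):
                gw = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * _activate_grad(
                        acts[layer], config.activation)
                weights[layer] = weights[layer] * decay - lr * gw
                if shrink > 0:
                    weights[layer] = np.sign(weights[layer]) * np.maximum(
                        np.abs(weights[layer]) - shrink, 0.0)
                biases[layer] = biases[layer] - lr * gb
        p_tr = _forward(x_tr, weights, biases, config.activation)[-1]
        p_va = _forward(x_va, weights, biases, config.activation)[-1]
        loss = -float(np.mean(np.log(p_tr[y_tr.astype(bool)] + 1e-12)))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}; "
                               f"reduce the learning rate ({lr})")
        acc_tr, rmse_tr = _metrics(p_tr, y_tr)
        acc_va, rmse_va = _metrics(p_va, y_va)
        history.append({"epoch": epoch + 1, "loss": loss,
                        "train_accuracy": acc_tr, "train_rmse": rmse_tr,
                        "validation_accuracy": acc_va, "validation_rmse": rmse_va})

    hist = pd.DataFrame(history)
    last = hist.iloc[-1]
    return TrainedModel(config=config, classes=list(classes), mu=mu, sigma=sigma,
                        weights=weights, biases=biases,
                        train_accuracy=float(last.train_accuracy),
                        validation_accuracy=float(last.validation_accuracy),
                        train_rmse=float(last.train_rmse),
                        validation_rmse=float(last.validation_rmse),
                        history=hist)


def predict(model: TrainedModel, features: FeatureMatrix) -> list[Prediction]:
    """Softmax-normalized class scores; argmax ties resolve to the
    alphabetically first class (class list is kept sorted)."""
    if features.n_features != len(model.mu):
        raise ValueError("feature width does not match the trained model")
    x = (features.values - model.mu) / model.sigma
    scores = _forward(x, model.weights, model.biases, model.config.activation)[-1]
    out = []
    for rid, row in zip(features.run_ids, scores):
        out.append(Prediction(run_id=rid, predicted=model.classes[int(row.argmax())],
                              scores=row, classes=model.classes))
    return out


def grid_search(matrix: FeatureMatrix, grid: GridSearchSpec,
                split: SplitSpec | None = None,
                classes: list[str] | None = None,
                ) -> tuple[pd.DataFrame, TrainedModel]:
    """Seeded random exploration of the hyperparameter grid.

    Configurations are visited in a seeded random order until the
    model-count or runtime stopping criterion fires.  Returns the candidate
    summary table and the selected best model.
    """
    if not grid.params:
        raise ValueError("empty parameter grid")
    keys = sorted(grid.params)
    combos = list(itertools.product(*(grid.params[k] for k in keys)))
    rng = np.random.default_rng(grid.seed)
    order = rng.permutation(len(combos))

    train, validation = split_corpus(matrix, split)
    t0 = time.monotonic()
    summaries = []
    models: list[TrainedModel] = []
    for i, pos in enumerate(order):
        if i >= grid.max_models:
            break
        if grid.max_runtime_s is not None and time.monotonic() - t0 > grid.max_runtime_s:
            break
        params = dict(zip(keys, combos[pos]))
        if "hidden_layers" in params:
            params["hidden_layers"] = tuple(params["hidden_layers"])
        config = replace(NetConfig(), seed=i, **params)
        tic = time.monotonic()
        model = train_fann(config, train, validation, classes=classes)
        summaries.append({"model_index": i, **{k: params.get(k) for k in keys},
                          "train_accuracy": model.train_accuracy,
                          "validation_accuracy": model.validation_accuracy,
                          "train_rmse": model.train_rmse,
                          "validation_rmse": model.validation_rmse,
                          "seconds": time.monotonic() - tic})
        models.append(model)
    if not models:
        raise RuntimeError("grid search produced no successful fits")
    table = pd.DataFrame(summaries)
    best_pos = min(range(len(models)),
                   key=lambda i: (-models[i].validation_accuracy,
                                  models[i].validation_rmse, i))
    return table, models[best_pos]


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a self-describing JSON document."""
    doc = {
        "format": "meltid-fann", "version": 1,
        "config": asdict(model.config),
        "classes": model.classes,
        "mu": model.mu.tolist(), "sigma": model.sigma.tolist(),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "metrics": {"train_accuracy": model.train_accuracy,
                    "validation_accuracy": model.validation_accuracy,
                    "train_rmse": model.train_rmse,
                    "validation_rmse": model.validation_rmse},
        "history": model.history.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "meltid-fann":
        raise ValueError(f"{path} is not a saved model")
    cfg = doc["config"]
    cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
    metrics = doc["metrics"]
    return TrainedModel(config=NetConfig(**cfg), classes=doc["classes"],
                        mu=np.asarray(doc["mu"]), sigma=np.asarray(doc["sigma"]),
                        weights=[np.asarray(w) for w in doc["weights"]],
                        biases=[np.asarray(b) for b in doc["biases"]],
                        train_accuracy=metrics["train_accuracy"],
                        validation_accuracy=metrics["validation_accuracy"],
                        train_rmse=metrics["train_rmse"],
                        validation_rmse=metrics["validation_rmse"],
                        history=pd.DataFrame(doc["history"]))
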