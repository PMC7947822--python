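"""Dense feed-forward network with elastic-net weight regularization.

Two tasks share one architecture: a five-class softmax classifier of
retention mechanisms, and a linear-head predictor of the 5m per-tissue OU
parameters (theta_p, theta_c, theta_a, log10 alpha, log10 sigma2).  Hidden
layers use ReLU; the first hidden layer has 256 units and each subsequent
layer half as many.  With L = 0 hidden layers the classifier reduces to
multinomial regression and the predictor to linear regression.

Training minimizes

    J = mean_i L(yhat_i, y_i) + lambda * sum_w [(1-gamma) w^2 + gamma |w|]

over all layer weights (biases unpenalized), where L is categorical
cross-entropy (classification) or the residual sum of squares over the K
outputs (prediction), using minibatch Adam.  Hyperparameters (L, lambda,
gamma) are chosen by stratified five-fold cross-validation on the
unpenalized held-out loss.

Features are z-scored with training-set statistics before entering the
network (rank features span [1, |G|+1] while moment features are O(1);
penalized training is scale-sensitive).  The statistics travel with the
model and are applied at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "CVResult",
    "forward",
    "cost",
    "train",
    "make_stratified_folds",
    "cross_validate",
    "classify",
    "predict_parameters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training settings.

    Defaults follow the standard protocol: Adam (lr 1e-3, beta1 0.9,
    beta2 0.999, eps 1e-8), minibatches of 5,000, 500 epochs, first hidden
    width 256 halving per layer.
    """

    task: str  # "classify" | "predict"
    input_dim: int
    output_dim: int
    n_hidden: int = 2
    lambda_: float = 0.0
    gamma: float = 0.0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 5000
    epochs: int = 500
    first_width: int = 256
    standardize: bool = True
    scalar_bias_per_layer: bool = False
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.task not in ("classify", "predict"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_hidden not in (0, 1, 2, 3):
            raise ValueError("n_hidden must be in {0,1,2,3}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")

    @property
    def hidden_widths(self) -> list[int]:
        return [self.first_width // (2**i) for i in range(self.n_hidden)]

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_widths, self.output_dim]


@dataclass
class TrainedModel:
    """Fitted network: weights, biases, feature-scaling statistics, config."""

    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    feature_version: str = "oudup-features-v1"
    final_cost: float = float("nan")

    def __post_init__(self) -> None:
        dims = self.config.layer_dims
        for i, w in enumerate(self.weights):
            if w.shape != (dims[i], dims[i + 1]):
                raise ValueError(f"weight {i} has shape {w.shape}, expected "
                                 f"{(dims[i], dims[i + 1])}")


@dataclass
class CVResult:
    """Cross-validation grid with mean held-out losses and the argmin."""

    grid: list[dict]
    selected: dict

    def __post_init__(self) -> None:
        best = min(self.grid, key=lambda g: g["mean_loss"])
        if best["mean_loss"] < self.selected["mean_loss"]:
            raise ValueError("selected grid point is not the argmin")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _standardize(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    if not model.config.standardize:
        return x
    return (x - model.feature_mean) / model.feature_sd


def _forward_pass(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    x: np.ndarray,
    task: str,
    keep_activations: bool = False,
):
    acts = [x]
    a = x
    n_layers = len(weights)
    for i in range(n_layers - 1):
        a = np.maximum(a @ weights[i] + biases[i], 0.0)
        if keep_activations:
            acts.append(a)
    z = a @ weights[-1] + biases[-1]
    out = _softmax(z) if task == "classify" else z
    return (out, acts) if keep_activations else out


def forward(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Score feature rows: class probabilities (classify) or parameter
    estimates (predict).  Accepts a single p-vector or an (n, p) matrix."""
    x = np.asarray(x, dtype=model.weights[0].dtype)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature width {x.shape[1]} != model input_dim {model.config.input_dim}"
        )
    out = _forward_pass(
        model.weights, model.biases, _standardize(model, x), model.config.task
    )
    return out[0] if squeeze else out


def _mean_loss(task: str, yhat: np.ndarray, y: np.ndarray) -> float:
    if task == "classify":
        p = np.clip(yhat[np.arange(len(yhat)), y.astype(int)], 1e-12, None)
        return float(-np.mean(np.log(p)))
    return float(np.mean(((yhat - y) ** 2).sum(axis=1)))


def _penalty(weights: list[np.ndarray], lambda_: float, gamma: float) -> float:
    if lambda_ == 0.0:
        return 0.0
    tot = 0.0
    for w in weights:
        tot += (1.0 - gamma) * float((w**2).sum()) + gamma * float(np.abs(w).sum())
    return lambda_ * tot


def cost(
    model: TrainedModel,
    x: np.ndarray,
    y: np.ndarray,
    lambda_: float | None = None,
    gamma: float | None = None,
) -> float:
    """Penalized cost J: mean per-observation loss plus the elastic-net
    penalty over all layer weights (biases unpenalized)."""
    lambda_ = model.config.lambda_ if lambda_ is None else lambda_
    gamma = model.config.gamma if gamma is None else gamma
    yhat = forward(model, x)
    return _mean_loss(model.config.task, np.atleast_2d(yhat), y) + _penalty(
        model.weights, lambda_, gamma
    )


def _init_params(config: NetworkConfig, rng: np.random.Generator):
    dims = config.layer_dims
    dt = np.dtype(config.dtype)
    weights, biases = [], []
    for i in range(len(dims) - 1):
        limit = np.sqrt(6.0 / (dims[i] + dims[i + 1]))  # Glorot uniform
        weights.append(rng.uniform(-limit, limit, size=(dims[i], dims[i + 1])).astype(dt))
        b_shape = (1,) if config.scalar_bias_per_layer else (dims[i + 1],)
        biases.append(np.zeros(b_shape, dtype=dt))
    return weights, biases


def train(
    features: np.ndarray,
    labels_or_targets: np.ndarray,
    config: NetworkConfig,
    rng_seed: int | np.random.Generator = 0,
) -> TrainedModel:
    """Fit the network with minibatch Adam; deterministic given the seed.

    ``labels_or_targets`` is an integer class vector for ``task='classify'``
    or an (n, K) target matrix for ``task='predict'``.
    """
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    dt = np.dtype(config.dtype)
    x = np.asarray(features, dtype=dt)
    n, p = x.shape
    if p != config.input_dim:
        raise ValueError(f"feature width {p} != config.input_dim {config.input_dim}")

    if config.task == "classify":
        y_int = np.asarray(labels_or_targets).astype(int)
        if y_int.shape != (n,):
            raise ValueError("classification labels must be an (n,) integer vector")
        y = np.zeros((n, config.output_dim), dtype=dt)
        y[np.arange(n), y_int] = 1.0
    else:
        y = np.asarray(labels_or_targets, dtype=dt)
        if y.shape != (n, config.output_dim):
            raise ValueError("prediction targets must be (n, output_dim)")

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    if config.standardize:
        x = (x - mean) / sd

    weights, biases = _init_params(config, rng)
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]

    lam, gam = config.lambda_, config.gamma
    lr, b1, b2, eps = config.learning_rate, config.beta1, config.beta2, config.eps
    step = 0
    last_epoch_loss = float("nan")
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            nb = len(idx)

            acts = [xb]
            a = xb
            for i in range(len(weights) - 1):
                a = np.maximum(a @ weights[i] + biases[i], 0.0)
                acts.append(a)
            z = a @ weights[-1] + biases[-1]

            if config.task == "classify":
                yhat = _softmax(z)
                batch_loss = -np.mean(
                    np.log(np.clip((yhat * yb).sum(axis=1), 1e-12, None))
                )
                delta = (yhat - yb) / nb
            else:
                yhat = z
                r = yhat - yb
                batch_loss = float(np.mean((r**2).sum(axis=1)))
                delta = 2.0 * r / nb
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}, step {step}"
                )
            epoch_loss += batch_loss * nb

            step += 1
            for i in range(len(weights) - 1, -1, -1):
                gw = acts[i].T @ delta
                if lam > 0.0:
                    gw = gw + lam * (
                        2.0 * (1.0 - gam) * weights[i] + gam * np.sign(weights[i])
                    )
                gb = (
                    delta.sum(dtype=dt, keepdims=True).reshape(1)
                    if config.scalar_bias_per_layer
                    else delta.sum(axis=0)
                )
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0.0)

                # Adam update
                t = step
                for g, wv, mom, vel in ((gw, weights, mw, vw), (gb, biases, mb, vb)):
                    mom[i] = b1 * mom[i] + (1 - b1) * g
                    vel[i] = b2 * vel[i] + (1 - b2) * g * g
                    mhat = mom[i] / (1 - b1**t)
                    vhat = vel[i] / (1 - b2**t)
                    wv[i] = wv[i] - lr * mhat / (np.sqrt(vhat) + eps)

        last_epoch_loss = float(epoch_loss) / n

    model = TrainedModel(
        config=config,
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_sd=sd,
        final_cost=last_epoch_loss + _penalty(weights, lam, gam),
    )
    return model


def make_stratified_folds(
    strata: np.ndarray, n_folds: int, rng: int | np.random.Generator = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-balanced fold split: within each stratum, observations are
    shuffled and dealt round-robin into ``n_folds`` validation sets."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    strata = np.asarray(strata)
    fold_of = np.empty(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    folds = []
    for f in range(n_folds):
        val = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        folds.append((tr, val))
    return folds


def cross_validate(
    features: np.ndarray,
    labels_or_targets: np.ndarray,
    grid: list[dict],
    base_config: NetworkConfig,
    rng_seed: int | np.random.Generator = 0,
    strata: np.ndarray | None = None,
    n_folds: int = 5,
) -> CVResult:
    """Stratified k-fold CV over a grid of {n_hidden, lambda_, gamma}.

    The held-out metric is the task's unpenalized mean loss.  ``strata``
    defaults to the class labels for classification and must be supplied for
    the predictor when class balance across folds is wanted.  Fold membership
    is fixed across grid points, so duplicated grid points score identically.
    """
    if not grid:
        raise ValueError("grid is empty")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    if strata is None:
        if base_config.task != "classify":
            strata = np.zeros(len(features), dtype=int)
        else:
            strata = np.asarray(labels_or_targets)
    folds = make_stratified_folds(strata, n_folds, rng)
    # one seed per fold, shared across grid points: duplicated grid points
    # (and different hyperparameters) see identical folds and initializations
    fold_seeds = rng.integers(0, 2**31 - 1, size=n_folds)

    y = np.asarray(labels_or_targets)
    results = []
    for gi, point in enumerate(grid):
        cfg = replace(base_config, **point)
        fold_losses = []
        for fi, (tr, val) in enumerate(folds):
            model = train(features[tr], y[tr], cfg, rng_seed=int(fold_seeds[fi]))
            yhat = forward(model, np.asarray(features)[val])
            fold_losses.append(_mean_loss(cfg.task, yhat, y[val]))
        results.append(
            {**point, "mean_loss": float(np.mean(fold_losses)), "fold_losses": fold_losses}
        )
    selected = min(results, key=lambda g: g["mean_loss"])
    return CVResult(grid=results, selected=selected)


def classify(model: TrainedModel, features: np.ndarray):
    """Class probabilities and argmax hard calls (ties -> lowest class index)."""
    if model.config.task != "classify":
        raise ValueError("model task is not 'classify'")
    probs = np.atleast_2d(forward(model, features))
    return probs, probs.argmax(axis=1)


def predict_parameters(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-tissue parameter estimates ordered
    (theta_p, theta_c, theta_a, log10 alpha, log10 sigma2) per tissue."""
    if model.config.task != "predict":
        raise ValueError("model task is not 'predict'")
    return forward(model, features)


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize weights + scaling statistics + config into one .npz."""
    arrays = {
        "feature_mean": model.feature_mean,
        "feature_sd": model.feature_sd,
    }
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    meta = {
        "config": asdict(model.config),
        "n_layers": len(model.weights),
        "feature_version": model.feature_version,
        "final_cost": float(model.final_cost),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str, expected_feature_version: str | None = None) -> TrainedModel:
    """Load a model; refuses feature matrices of a different layout version
    when ``expected_feature_version`` is given."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if (
            expected_feature_version is not None
            and meta["feature_version"] != expected_feature_version
        ):
            raise ValueError(
                f"model was trained on feature layout {meta['feature_version']!r}, "
                f"got {expected_feature_version!r}"
            )
        n_layers = meta["n_layers"]
        model = TrainedModel(
            config=NetworkConfig(**meta["config"]),
            weights=[data[f"W{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            feature_mean=data["feature_mean"],
            feature_sd=data["feature_sd"],
            feature_version=meta["feature_version"],
            final_cost=meta["final_cost"],
        )
    return model
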