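"""From-scratch classifiers with verifiable gradients.

Two models drive the pipeline:

* an L2-regularized logistic regression fitted by damped Newton iterations
  (the scorer behind sensor ablation and Shapley attribution), and
* a multilayer perceptron with hidden layers 128/64/32, each block
  affine -> batch-norm -> ReLU -> dropout, a sigmoid output unit, mean binary
  cross-entropy plus an L2 weight penalty, trained with Adam.

Both expose explicit loss/gradient functions so correctness can be checked
against finite differences and brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EPS_LOG = 1e-12
BN_EPS = 1e-5


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass
class LogisticModel:
    weights: np.ndarray
    intercept: float
    ridge_penalty: float
    converged: bool
    iterations: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature count mismatch: model has {self.weights.shape[0]}, "
                f"input has {X.shape[1]}"
            )
        return _sigmoid(X @ self.weights + self.intercept)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.weights + self.intercept


def _logistic_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float
) -> float:
    z = X @ w + b
    # log(1 + exp(-|z|)) + max(z,0) - y*z is the stable NLL summand
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    return nll + 0.5 * lam * float(w @ w)


def fit_logistic(
    X,
    labels,
    ridge_penalty: float = 1.0,
    tolerance: float = 1e-8,
    max_iterations: int = 100,
    positive_label=1,
) -> LogisticModel:
    """Minimize the ridge-penalized logistic negative log-likelihood.

    The objective is sum-BCE + (lambda/2)||w||^2 with the intercept
    unpenalized, solved by damped Newton steps with step-halving; convergence
    when the penalized gradient norm falls below ``tolerance``.

    When the feature dimension exceeds the sample count, the fit is carried
    out in the row space of X (thin SVD): the ridge optimum has no component
    orthogonal to the data, so this reduction is exact and much faster for
    wide matrices such as 46 x 348.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = (np.asarray(labels).ravel() == positive_label).astype(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n, d = X.shape

    basis = None
    if d > n:
        # exact row-space reduction: w = V beta, ||w|| = ||beta||
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, bool)
        basis = vt[keep]  # (r, d)
        X_fit = X @ basis.T
    else:
        X_fit = X
    d_fit = X_fit.shape[1]

    w = np.zeros(d_fit)
    b = 0.0
    lam = ridge_penalty
    converged = False
    it = 0
    obj = _logistic_objective(X_fit, y, w, b, lam)
    for it in range(1, max_iterations + 1):
        p = _sigmoid(X_fit @ w + b)
        grad_w = X_fit.T @ (p - y) + lam * w
        grad_b = float(np.sum(p - y))
        gnorm = math.sqrt(float(grad_w @ grad_w) + grad_b**2)
        if gnorm < tolerance:
            converged = True
            break
        s_diag = np.maximum(p * (1 - p), 1e-10)
        Xs = X_fit * s_diag[:, None]
        H = np.empty((d_fit + 1, d_fit + 1))
        H[:d_fit, :d_fit] = X_fit.T @ Xs + lam * np.eye(d_fit)
        H[:d_fit, d_fit] = H[d_fit, :d_fit] = Xs.sum(axis=0)
        H[d_fit, d_fit] = s_diag.sum()
        step = np.linalg.solve(H, np.r_[grad_w, grad_b])
        # step-halving on the penalized objective
        t = 1.0
        for _ in range(50):
            w_new = w - t * step[:d_fit]
            b_new = b - t * step[d_fit]
            obj_new = _logistic_objective(X_fit, y, w_new, b_new, lam)
            if obj_new <= obj + 1e-14:
                break
            t *= 0.5
        w, b, obj = w_new, b_new, obj_new
    else:
        it = max_iterations
    if not converged:
        p = _sigmoid(X_fit @ w + b)
        grad_w = X_fit.T @ (p - y) + lam * w
        gnorm = math.sqrt(float(grad_w @ grad_w) + float(np.sum(p - y)) ** 2)
        converged = gnorm < tolerance
        if not converged:
            import warnings

            warnings.warn(
                f"logistic fit did not converge in {max_iterations} iterations "
                f"(gradient norm {gnorm:.3e})",
                stacklevel=2,
            )
    weights = basis.T @ w if basis is not None else w
    return LogisticModel(
        weights=weights,
        intercept=float(b),
        ridge_penalty=lam,
        converged=converged,
        iterations=it,
    )


def predict_proba_logistic(model: LogisticModel, X) -> np.ndarray:
    return model.predict_proba(np.asarray(getattr(X, "values", X), float))


# ---------------------------------------------------------------------------
# Multilayer perceptron


@dataclass(frozen=True)
class MlpConfig:
    """MLP architecture and optimization hyperparameters (study defaults)."""

    hidden_sizes: tuple[int, ...] = (128, 64, 32)
    l2_lambda: float = 0.001
    dropout_rate: float = 0.3
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class MlpLayer:
    W: np.ndarray
    b: np.ndarray
    gamma: np.ndarray | None = None  # batch-norm scale (hidden layers only)
    beta: np.ndarray | None = None
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None


@dataclass
class MlpModel:
    layers: list[MlpLayer]
    config: MlpConfig
    training_history: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.layers[0].W.shape[0]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(getattr(X, "values", X), float)
        probs, _ = mlp_forward(self, X, train=False)
        return probs


def init_mlp(n_features: int, config: MlpConfig) -> MlpModel:
    """Seeded He (fan-in) initialization; batch-norm starts neutral."""
    rng = np.random.default_rng(config.seed)
    sizes = [n_features, *config.hidden_sizes, 1]
    layers = []
    for i in range(len(sizes) - 1):
        fan_in, fan_out = sizes[i], sizes[i + 1]
        W = rng.standard_normal((fan_in, fan_out)) * math.sqrt(2.0 / fan_in)
        b = np.zeros(fan_out)
        if i < len(sizes) - 2:
            layers.append(
                MlpLayer(
                    W=W,
                    b=b,
                    gamma=np.ones(fan_out),
                    beta=np.zeros(fan_out),
                    run_mean=np.zeros(fan_out),
                    run_var=np.ones(fan_out),
                )
            )
        else:
            layers.append(MlpLayer(W=W, b=b))
    return MlpModel(layers=layers, config=config)


def mlp_forward(
    model: MlpModel,
    X: np.ndarray,
    train: bool,
    dropout_rng: np.random.Generator | None = None,
    update_running: bool = True,
) -> tuple[np.ndarray, list[dict]]:
    """Forward pass; hidden block order is affine -> batch-norm -> ReLU -> dropout.

    Train mode normalizes by batch statistics and applies seeded inverted
    dropout; inference mode uses running moments and no dropout.  Returns the
    sigmoid outputs and the per-layer cache backpropagation needs.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_inputs:
        raise ValueError("input width does not match the network")
    cfg = model.config
    if train and X.shape[0] < 2 and any(l.gamma is not None for l in model.layers):
        raise ValueError("batch of size 1 in train mode: batch variance undefined")
    a = X
    caches: list[dict] = []
    for li, layer in enumerate(model.layers):
        z = a @ layer.W + layer.b
        cache: dict = {"a_in": a, "z": z}
        if layer.gamma is not None:
            if train:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                if update_running:
                    m = cfg.bn_momentum
                    layer.run_mean = m * layer.run_mean + (1 - m) * mu
                    layer.run_var = m * layer.run_var + (1 - m) * var
            else:
                mu, var = layer.run_mean, layer.run_var
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            z_hat = (z - mu) * inv_std
            h = layer.gamma * z_hat + layer.beta
            cache.update(
                {"mu": mu, "var": var, "inv_std": inv_std, "z_hat": z_hat, "bn_train": train}
            )
            relu_in = h
            act = np.maximum(relu_in, 0.0)
            cache["relu_mask"] = relu_in > 0
            if train and cfg.dropout_rate > 0:
                rng = dropout_rng if dropout_rng is not None else np.random.default_rng(cfg.seed)
                keep = 1.0 - cfg.dropout_rate
                mask = (rng.random(act.shape) < keep) / keep
                act = act * mask
                cache["dropout_mask"] = mask
            a = act
        else:
            a = _sigmoid(z)
        caches.append(cache)
    return a.ravel(), caches


def mlp_loss_and_gradients(
    model: MlpModel,
    X: np.ndarray,
    labels: np.ndarray,
    train: bool = True,
    dropout_rng: np.random.Generator | None = None,
    update_running: bool = False,
) -> tuple[float, list[dict]]:
    """Mean BCE + lambda * sum ||W||^2, with gradients for every trainable tensor.

    Biases and batch-norm scale/shift are unpenalized.  Backpropagation runs
    through the dropout masks and (in train mode) through the batch statistics;
    in inference mode the running moments are constants, making the layer a
    fixed per-channel affine map — the configuration used for the
    finite-difference gradient check.
    """
    y = np.asarray(labels, dtype=float).ravel()
    probs, caches = mlp_forward(model, X, train=train, dropout_rng=dropout_rng,
                                update_running=update_running)
    n = len(y)
    p = np.clip(probs, EPS_LOG, 1.0 - EPS_LOG)
    lam = model.config.l2_lambda
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    loss += lam * sum(float(np.sum(l.W**2)) for l in model.layers)

    grads: list[dict] = [{} for _ in model.layers]
    # output layer: d loss / d z_out = (p - y) / n  (sigmoid + BCE)
    delta = ((probs - y) / n)[:, None]
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        cache = caches[li]
        if layer.gamma is not None:
            if "dropout_mask" in cache:
                delta = delta * cache["dropout_mask"]
            delta = delta * cache["relu_mask"]
            grads[li]["gamma"] = np.sum(delta * cache["z_hat"], axis=0)
            grads[li]["beta"] = np.sum(delta, axis=0)
            dz_hat = delta * layer.gamma
            if cache["bn_train"]:
                m = delta.shape[0]
                z_hat, inv_std = cache["z_hat"], cache["inv_std"]
                # backprop through batch mean and variance
                delta = (
                    inv_std
                    / m
                    * (
                        m * dz_hat
                        - np.sum(dz_hat, axis=0)
                        - z_hat * np.sum(dz_hat * z_hat, axis=0)
                    )
                )
            else:
                delta = dz_hat * cache["inv_std"]
        grads[li]["W"] = cache["a_in"].T @ delta + 2.0 * lam * layer.W
        grads[li]["b"] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ layer.W.T
    return loss, grads


def train_mlp(X, labels, config: MlpConfig | None = None, positive_label=1) -> MlpModel:
    """Train the MLP with Adam over seeded shuffled mini-batches.

    Adam uses beta1=0.9, beta2=0.999, eps=1e-8; the final incomplete
    mini-batch is used, not dropped.  Aborts on a non-finite loss.
    """
    if config is None:
        config = MlpConfig()
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = (np.asarray(labels).ravel() == positive_label).astype(float)
    model = init_mlp(X.shape[1], config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    adam_m = [
        {k: np.zeros_like(getattr(l, k)) for k in ("W", "b", "gamma", "beta") if getattr(l, k) is not None}
        for l in model.layers
    ]
    adam_v = [{k: np.zeros_like(v) for k, v in lm.items()} for lm in adam_m]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2 and config.hidden_sizes:
                # a singleton batch has no batch variance; fold it into stats-free skip
                continue
            xb, yb = X[idx], y[idx]
            loss, grads = mlp_loss_and_gradients(
                model, xb, yb, train=True, dropout_rng=dropout_rng, update_running=True
            )
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}, batch {start // config.batch_size}"
                )
            epoch_loss += loss
            n_batches += 1
            t += 1
            for li, layer in enumerate(model.layers):
                for key, g in grads[li].items():
                    adam_m[li][key] = b1 * adam_m[li][key] + (1 - b1) * g
                    adam_v[li][key] = b2 * adam_v[li][key] + (1 - b2) * g**2
                    m_hat = adam_m[li][key] / (1 - b1**t)
                    v_hat = adam_v[li][key] / (1 - b2**t)
                    param = getattr(layer, key)
                    setattr(
                        layer, key,
                        param - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps),
                    )
        model.training_history.append(epoch_loss / max(n_batches, 1))
    return model
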