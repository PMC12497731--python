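"""Density-weighted least-squares support vector regression.

The LSSVM replaces the SVM's inequality constraints with equality
constraints and squared slacks, so training reduces to one (n+1) x (n+1)
linear saddle system instead of a quadratic program:

    [ 0   1^T ] [ b ]   [ 0 ]
    [ 1  K + D] [ a ] = [ y ],   D = diag(1 / (gamma * w_i)),

with K the RBF Gram matrix K(x, z) = exp(-||x - z||^2 / (2 sigma^2)) and
w_i > 0 per-sample weights (density weights from the adaptive KDE; w = 1
recovers the standard unweighted LSSVM). Prediction is
f(x) = sum_i a_i K(x, x_i) + b.

Inputs are min-max normalized to [0, 1] and targets z-scored inside the
model (statistics fitted on training data only), so the hyperparameter
search bounds are scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LSSVMModel", "rbf_kernel", "train_lssvm", "predict", "save_model", "load_model"]


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix with the exp(-||x-z||^2 / (2 sigma^2)) convention."""
    sq = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * sigma**2))


@dataclass
class LSSVMModel:
    """Trained weighted LSSVM: kernel hyperparameters, dual solution and
    the normalization statistics needed to predict on raw-scale inputs."""

    gamma: float
    sigma: float
    alpha: np.ndarray
    bias: float
    X_train: np.ndarray  # normalized training inputs
    weights: np.ndarray
    x_min: np.ndarray
    x_range: np.ndarray
    y_mean: float
    y_std: float

    def __post_init__(self) -> None:
        if abs(self.alpha.sum()) > 1e-8 * max(1.0, np.abs(self.alpha).max()):
            raise ValueError("dual coefficients must sum to 0 (first KKT row)")
        if len(self.alpha) != len(self.X_train):
            raise ValueError("one dual coefficient per training sample required")


def _normalize_inputs(X: np.ndarray, x_min: np.ndarray, x_range: np.ndarray) -> np.ndarray:
    return (X - x_min) / x_range


def train_lssvm(X, y, gamma: float, sigma: float, weights=None) -> LSSVMModel:
    """Solve the weighted LSSVM dual system by one exact dense solve.

    A singular system gets one jitter retry (+1e-12 on the regularized Gram
    diagonal) before failing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 1 or len(y) != n:
        raise ValueError(f"inconsistent training shapes: X {X.shape}, y {y.shape}")
    if gamma <= 0 or sigma <= 0:
        raise ValueError(f"hyperparameters must be positive, got gamma={gamma}, sigma={sigma}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if len(w) != n or (w <= 0).any():
        raise ValueError("weights must be positive, one per training sample")

    x_min = X.min(axis=0)
    x_range = X.max(axis=0) - x_min
    x_range = np.where(x_range > 0, x_range, 1.0)  # constant feature: passthrough
    Xn = _normalize_inputs(X, x_min, x_range)
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=0))
    if y_std == 0:
        y_std = 1.0
    yn = (y - y_mean) / y_std

    K = rbf_kernel(Xn, Xn, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.diag(1.0 / (gamma * w))
    rhs = np.concatenate([[0.0], yn])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        A[1:, 1:] += 1e-12 * np.eye(n)
        sol = np.linalg.solve(A, rhs)  # second failure surfaces as LinAlgError
    bias, alpha = float(sol[0]), sol[1:]
    # project out solver round-off on the zero-sum KKT constraint
    alpha = alpha - alpha.mean()
    return LSSVMModel(
        gamma=float(gamma),
        sigma=float(sigma),
        alpha=alpha,
        bias=bias,
        X_train=Xn,
        weights=w,
        x_min=x_min,
        x_range=x_range,
        y_mean=y_mean,
        y_std=y_std,
    )


def predict(model: LSSVMModel, X) -> np.ndarray:
    """Evaluate f(x) = sum_i a_i K(x, x_i) + b on raw-scale inputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} != training dimension {model.X_train.shape[1]}"
        )
    Xn = _normalize_inputs(X, model.x_min, model.x_range)
    K = rbf_kernel(Xn, model.X_train, model.sigma)
    yn = K @ model.alpha + model.bias
    return yn * model.y_std + model.y_mean


# --------------------------------------------------------------------------
# JSON serialization (bit round-trip via float hex encoding)


def _enc(a: np.ndarray) -> list:
    return [float.hex(float(v)) for v in np.asarray(a, dtype=float).ravel()]


def _dec(values: list) -> np.ndarray:
    return np.array([float.fromhex(v) for v in values], dtype=float)


def save_model(model: LSSVMModel, path: str | Path) -> None:
    n, d = model.X_train.shape
    payload = {
        "format": "saltlax-lssvm/1",
        "gamma": model.gamma,
        "sigma": model.sigma,
        "bias": float.hex(model.bias),
        "alpha": _enc(model.alpha),
        "weights": _enc(model.weights),
        "X_train": _enc(model.X_train),
        "n_train": n,
        "n_features": d,
        "x_min": _enc(model.x_min),
        "x_range": _enc(model.x_range),
        "y_mean": float.hex(model.y_mean),
        "y_std": float.hex(model.y_std),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> LSSVMModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "saltlax-lssvm/1":
        raise ValueError(f"{path}: not a saltlax LSSVM model file")
    n, d = payload["n_train"], payload["n_features"]
    return LSSVMModel(
        gamma=payload["gamma"],
        sigma=payload["sigma"],
        alpha=_dec(payload["alpha"]),
        bias=float.fromhex(payload["bias"]),
        X_train=_dec(payload["X_train"]).reshape(n, d),
        weights=_dec(payload["weights"]),
        x_min=_dec(payload["x_min"]),
        x_range=_dec(payload["x_range"]),
        y_mean=float.fromhex(payload["y_mean"]),
        y_std=float.fromhex(payload["y_std"]),
    )
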