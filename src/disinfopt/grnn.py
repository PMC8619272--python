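"""Generalized regression neural network (Specht-style kernel regression).

A GRNN is a one-pass estimator: the prediction at a query point x is the
Gaussian-kernel-weighted average of the stored training targets,

    yhat(x) = sum_i y_i * exp(-||x - x_i||^2 / (2 sigma^2))
            / sum_i       exp(-||x - x_i||^2 / (2 sigma^2)),

with a single spread parameter sigma controlling the trade-off between
interpolation (sigma -> 0) and the global mean (sigma -> infinity).
Distances are taken in per-feature min-max-normalized space so that the
three protocol axes (0-15 % NaOCl, 0-30 % H2O2, 0-20 min) contribute
comparably.  sigma is chosen by leave-one-out RMSE over a log grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import ReplicateObservation, Treatment, observations_to_arrays

__all__ = ["Scaler", "GRNNModel", "fit_grnn", "select_sigma", "grnn_predict",
           "DEFAULT_SIGMA_GRID"]

# 30 log-spaced spread candidates spanning near-interpolation to heavy smoothing
DEFAULT_SIGMA_GRID: np.ndarray = np.geomspace(0.02, 2.0, 30)


@dataclass(frozen=True)
class Scaler:
    """Per-feature min-max normalization fitted on training inputs.

    Degenerate features (max == min) map to constant 0 so they drop out of
    the distance.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        mins = X.min(axis=0)
        maxs = X.max(axis=0)
        degenerate = maxs == mins
        if degenerate.any():
            warnings.warn(
                f"feature(s) {np.flatnonzero(degenerate).tolist()} are constant "
                "in training data; they are mapped to 0 and carry no distance",
                stacklevel=2,
            )
        return cls(mins=mins, maxs=maxs)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        out = (X - self.mins) / safe
        return np.where(span == 0, 0.0, out)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z * (self.maxs - self.mins) + self.mins


@dataclass(frozen=True)
class GRNNModel:
    """Fitted GRNN: normalized training points, targets, spread, scaler."""

    training_inputs: np.ndarray  # (n, d), already normalized
    training_targets: np.ndarray  # (n,), contamination %
    sigma: float
    scaler: Scaler

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if len(self.training_inputs) != len(self.training_targets):
            raise ValueError("inputs and targets length mismatch")
        if len(self.training_targets) == 0:
            raise ValueError("need at least one training point")

    def predict(self, X) -> np.ndarray:
        """Predict contamination % at one or more treatments.

        Accepts a :class:`Treatment`, a length-3 vector, or an (m, 3)
        matrix of raw (unnormalized) protocol coordinates; returns an
        (m,) array.
        """
        if isinstance(X, Treatment):
            X = X.as_array()
        Z = self.scaler.transform(X)
        return _kernel_predict(self.training_inputs, self.training_targets,
                               Z, self.sigma)

    def save(self, path: str | Path) -> None:
        doc = {
            "sigma": self.sigma,
            "scaler": {"mins": self.scaler.mins.tolist(),
                       "maxs": self.scaler.maxs.tolist()},
            "training_inputs": self.training_inputs.tolist(),
            "training_targets": self.training_targets.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GRNNModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            training_inputs=np.asarray(doc["training_inputs"], dtype=float),
            training_targets=np.asarray(doc["training_targets"], dtype=float),
            sigma=float(doc["sigma"]),
            scaler=Scaler(np.asarray(doc["scaler"]["mins"], dtype=float),
                          np.asarray(doc["scaler"]["maxs"], dtype=float)),
        )


def _kernel_predict(Xtr: np.ndarray, ytr: np.ndarray, Z: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Gaussian-kernel weighted average of ytr at normalized queries Z."""
    d2 = ((Z[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
    expo = -d2 / (2.0 * sigma * sigma)
    # subtract the per-query max exponent so the nearest point's weight is 1
    w = np.exp(expo - expo.max(axis=1, keepdims=True))
    denom = w.sum(axis=1)
    out = np.empty(len(Z))
    ok = denom > 0
    out[ok] = (w[ok] @ ytr) / denom[ok]
    if not ok.all():  # all weights underflowed: nearest-neighbor fallback
        nearest = d2[~ok].argmin(axis=1)
        out[~ok] = ytr[nearest]
    return out


def grnn_predict(model: GRNNModel, treatment) -> float:
    """Predicted contamination % for a single treatment."""
    return float(model.predict(treatment)[0])


def loo_rmse(X_norm: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Leave-one-out RMSE of the GRNN at a given spread."""
    n = len(y)
    d2 = ((X_norm[:, None, :] - X_norm[None, :, :]) ** 2).sum(axis=2)
    expo = -d2 / (2.0 * sigma * sigma)
    np.fill_diagonal(expo, -np.inf)
    w = np.exp(expo - expo.max(axis=1, keepdims=True))
    denom = w.sum(axis=1)
    pred = np.empty(n)
    ok = denom > 0
    pred[ok] = (w[ok] @ y) / denom[ok]
    if not ok.all():
        d2_loo = d2.copy()
        np.fill_diagonal(d2_loo, np.inf)
        pred[~ok] = y[d2_loo[~ok].argmin(axis=1)]
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def select_sigma(
    train_observations: Sequence[ReplicateObservation],
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> float:
    """Spread minimizing leave-one-out RMSE; ties go to the larger (smoother) sigma."""
    grid = np.asarray(list(sigma_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma_grid is empty")
    if (grid <= 0).any():
        raise ValueError("sigma_grid must contain positive values only")
    obs = list(train_observations)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to select sigma")
    X, y = observations_to_arrays(obs)
    scaler = Scaler.fit(X)
    Z = scaler.transform(X)
    scores = np.array([loo_rmse(Z, y, s) for s in grid])
    best = scores.min()
    # ties (within float noise) broken toward the largest qualifying sigma
    return float(grid[np.flatnonzero(scores <= best + 1e-12).max()])


def fit_grnn(
    train_observations: Sequence[ReplicateObservation],
    sigma: float | None = None,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
) -> GRNNModel:
    """Fit a GRNN on replicate observations.

    The scaler is fitted on the training inputs only.  If ``sigma`` is not
    given it is selected by leave-one-out RMSE over ``sigma_grid``.
    """
    obs = list(train_observations)
    if not obs:
        raise ValueError("need at least one training observation")
    if sigma is None:
        sigma = select_sigma(obs, sigma_grid) if len(obs) >= 2 else 0.5
    X, y = observations_to_arrays(obs)
    scaler = Scaler.fit(X)
    return GRNNModel(
        training_inputs=scaler.transform(X),
        training_targets=y,
        sigma=float(sigma),
        scaler=scaler,
    )
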