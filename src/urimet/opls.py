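"""OPLS-DA: orthogonal projections to latent structures, single response.

Implements the NIPALS O-PLS recipe with sequential orthogonal deflation
(Trygg-Wold style). For each of K orthogonal rounds on the current X:

    w  = X'y / ||X'y||          predictive weight candidate
    t  = Xw                      predictive score candidate
    p  = X't / (t't)             loading
    wo = p - (w'p) w, normalized orthogonal weight
    to = X wo                    orthogonal score
    po = X'to / (to'to)          orthogonal loading
    X <- X - to po'              deflate

After K rounds the predictive component (w, t_p, p_p, q = y't_p/(t_p't_p))
is taken from the deflated X. The class response is encoded 0/1 and
centered internally, so raw predictions live on the 0/1 scale and a 0.5
cut-off separates the classes; ties at the cut-off classify as case.

Q2 (the cross-validated analogue of R2Y) is 1 - PRESS/SS over stratified,
seeded folds; the blinded-holdout validator reproduces the one-third
per-class split with training-only scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import ScalingParams, pareto_scale, apply_scaling

__all__ = [
    "OplsModel",
    "fit_opls",
    "predict",
    "classify",
    "cross_validate_q2",
    "holdout_validate",
    "CUTOFF",
]

CUTOFF = 0.5


@dataclass
class OplsModel:
    """A fitted OPLS model: one predictive + n_orth orthogonal components."""

    w: np.ndarray            # predictive weights, unit norm
    p_p: np.ndarray          # predictive loadings
    t_p: np.ndarray          # training predictive scores
    q: float                 # y-loading (scalar, single response)
    W_o: np.ndarray          # (n_features, K) orthogonal weights, unit columns
    P_o: np.ndarray          # (n_features, K) orthogonal loadings
    T_o: np.ndarray          # (n_samples, K) training orthogonal scores
    n_orth: int
    y_mean: float
    r2y: float
    q2: float | None = None
    scaling: ScalingParams | None = None

    def to_json(self, path: str | Path, **provenance) -> None:
        obj = {
            "w": self.w.tolist(),
            "p_p": self.p_p.tolist(),
            "t_p": self.t_p.tolist(),
            "q": self.q,
            "W_o": self.W_o.tolist(),
            "P_o": self.P_o.tolist(),
            "T_o": self.T_o.tolist(),
            "n_orth": self.n_orth,
            "y_mean": self.y_mean,
            "r2y": self.r2y,
            "q2": self.q2,
            "provenance": provenance,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "OplsModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            w=np.array(obj["w"]),
            p_p=np.array(obj["p_p"]),
            t_p=np.array(obj["t_p"]),
            q=obj["q"],
            W_o=np.array(obj["W_o"]).reshape(len(obj["w"]), -1),
            P_o=np.array(obj["P_o"]).reshape(len(obj["w"]), -1),
            T_o=np.array(obj["T_o"]).reshape(len(obj["t_p"]), -1),
            n_orth=obj["n_orth"],
            y_mean=obj["y_mean"],
            r2y=obj["r2y"],
            q2=obj.get("q2"),
        )


def fit_opls(
    X_scaled: np.ndarray,
    y: np.ndarray,
    n_orth: int = 3,
    scaling: ScalingParams | None = None,
) -> OplsModel:
    """Fit the OPLS model on a scaled matrix and 0/1 class vector.

    X is assumed mean-centered/scaled; y is centered internally and its
    mean stored so predictions return to the 0/1 scale. With n_orth = 0
    this reduces to a one-component NIPALS PLS1 fit.
    """
    X = np.asarray(X_scaled, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y length must match row count")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; cannot fit a discriminant model")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if n_orth > 0 and n_orth >= np.linalg.matrix_rank(X):
        raise ValueError(f"n_orth={n_orth} must be < rank(X)")
    y_mean = float(y.mean())
    yc = y - y_mean

    W_o = np.zeros((p, n_orth))
    P_o = np.zeros((p, n_orth))
    T_o = np.zeros((n, n_orth))
    for k in range(n_orth):
        w = X.T @ yc
        w /= np.linalg.norm(w)
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            raise ValueError("orthogonal variation exhausted; reduce n_orth")
        w_o /= nrm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X -= np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o

    w = X.T @ yc
    w /= np.linalg.norm(w)
    t_p = X @ w
    p_p = X.T @ t_p / (t_p @ t_p)
    q = float(yc @ t_p / (t_p @ t_p))
    y_hat = q * t_p + y_mean
    ss = float(((y - y_mean) ** 2).sum())
    r2y = 1.0 - float(((y - y_hat) ** 2).sum()) / ss
    return OplsModel(
        w=w, p_p=p_p, t_p=t_p, q=q, W_o=W_o, P_o=P_o, T_o=T_o,
        n_orth=n_orth, y_mean=y_mean, r2y=r2y, scaling=scaling,
    )


def predict(
    model: OplsModel, X_new_scaled: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict new scaled samples: remove orthogonal variation, then project.

    Returns (y_hat, t_p_new, T_o_new). y_hat lives on the training 0/1
    label scale.
    """
    X = np.asarray(X_new_scaled, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.w.size})"
        )
    X = X.copy()
    T_o_new = np.zeros((X.shape[0], model.n_orth))
    for k in range(model.n_orth):
        t_o = X @ model.W_o[:, k]
        X -= np.outer(t_o, model.P_o[:, k])
        T_o_new[:, k] = t_o
    t_p = X @ model.w
    y_hat = model.q * t_p + model.y_mean
    return y_hat, t_p, T_o_new


def classify(y_hat: np.ndarray | float, cutoff: float = CUTOFF) -> np.ndarray:
    """Hard class labels from predicted responses; y_hat >= cutoff -> case (1)."""
    return (np.asarray(y_hat, dtype=float) >= cutoff).astype(int)


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal shuffled within-class indices round-robin into n_folds folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate_q2(
    X_scaled: np.ndarray,
    y: np.ndarray,
    n_orth: int = 3,
    n_folds: int = 7,
    seed: int = 0,
) -> float:
    """Q2 = 1 - PRESS/SS by stratified, seeded k-fold cross-validation.

    Each fold is held out once; the model refit on the remainder predicts
    it. A training partition missing a class triggers a warning and a
    reshuffled refold (error after 10 attempts).
    """
    X = np.asarray(X_scaled, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        folds = _stratified_folds(y, n_folds, rng)
        ok = all(
            np.ptp(y[np.setdiff1d(np.arange(y.size), f)]) > 0
            for f in folds
            if f.size
        )
        if ok:
            break
        warnings.warn("a cross-validation fold lacked both classes; refolding")
    else:
        raise ValueError("could not build folds with both classes after 10 attempts")
    press = 0.0
    for fold in folds:
        if fold.size == 0:
            continue
        train = np.setdiff1d(np.arange(y.size), fold)
        model = fit_opls(X[train], y[train], n_orth=n_orth)
        y_hat, _, _ = predict(model, X[fold])
        press += float(((y[fold] - y_hat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss


def holdout_split(
    y: np.ndarray, holdout_fraction: float = 1 / 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified blinded-holdout split; per-class holdout count is
    floor(n_class * fraction) (so 156/92 at one third gives 52 + 30 held
    out and 104 + 62 for training). Returns (train_idx, holdout_idx)."""
    y = np.asarray(y).ravel()
    rng = np.random.default_rng(seed)
    hold: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_hold = int(idx.size * holdout_fraction)
        if n_hold == 0 or n_hold == idx.size:
            raise ValueError(f"class {cls} too small to split at fraction {holdout_fraction}")
        rng.shuffle(idx)
        hold.extend(idx[:n_hold].tolist())
    hold_idx = np.array(sorted(hold), dtype=int)
    train_idx = np.setdiff1d(np.arange(y.size), hold_idx)
    return train_idx, hold_idx


def holdout_validate(
    X: np.ndarray,
    y: np.ndarray,
    holdout_fraction: float = 1 / 3,
    n_orth: int = 3,
    seed: int = 0,
    cutoff: float = CUTOFF,
    n_folds: int = 7,
) -> tuple[OplsModel, dict]:
    """Train on a stratified 2/3, predict the blinded 1/3 at the cut-off.

    X is the UNSCALED binned matrix: scaling parameters are estimated on
    the training partition only and applied to the holdout. Returns the
    fitted model (with training Q2) and a dict of per-class correct/total
    counts plus the index partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    train_idx, hold_idx = holdout_split(y, holdout_fraction, seed)
    X_train_scaled, params = pareto_scale(X[train_idx])
    model = fit_opls(X_train_scaled, y[train_idx], n_orth=n_orth, scaling=params)
    model.q2 = cross_validate_q2(X_train_scaled, y[train_idx], n_orth, n_folds, seed)
    X_hold_scaled = apply_scaling(X[hold_idx], params)
    y_hat, _, _ = predict(model, X_hold_scaled)
    pred = classify(y_hat, cutoff)
    truth = y[hold_idx]
    counts = {
        "control_correct": int(((truth == 0) & (pred == 0)).sum()),
        "control_total": int((truth == 0).sum()),
        "case_correct": int(((truth == 1) & (pred == 1)).sum()),
        "case_total": int((truth == 1).sum()),
        "train_idx": train_idx,
        "holdout_idx": hold_idx,
        "y_hat_holdout": y_hat,
    }
    return model, counts
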