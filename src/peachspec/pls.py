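"""PLS1 regression with cross-validated latent-variable selection.

The regression core is NIPALS PLS1 on mean-centred data (no column
scaling: SNV already normalises each spectrum, and autoscaling columns
would distort the band structure).  The number of latent variables (LVs)
is chosen by k-fold cross-validation, minimising the pooled held-out
RMSE (RMSECV); ties break toward fewer LVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "select_lv_by_cv"]

#: hard cap on latent variables
MAX_LV_DEFAULT = 20


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``coefficients``/``intercept`` are on the original (uncentred) scale,
    so predictions are simply ``X @ coefficients + intercept``.  The
    weight/loading matrices are retained so the coefficient vector for
    any smaller number of LVs can be reconstructed.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, n_lv) normalised NIPALS weights W
    x_loadings: np.ndarray  # (p, n_lv) loadings P
    y_loadings: np.ndarray  # (n_lv,) loadings q
    coefficients: np.ndarray  # (p,)
    intercept: float
    wavelength_indices: np.ndarray | None = None

    def coefficients_for(self, n_lv: int) -> tuple[np.ndarray, float]:
        """Coefficient vector and intercept using only the first
        ``n_lv`` latent variables."""
        if not 0 <= n_lv <= self.n_lv:
            raise InvalidParameterError(f"n_lv must lie in [0, {self.n_lv}]")
        if n_lv == 0:
            return np.zeros_like(self.x_mean), float(self.y_mean)
        w = self.weights[:, :n_lv]
        p = self.x_loadings[:, :n_lv]
        q = self.y_loadings[:n_lv]
        b = w @ np.linalg.solve(p.T @ w, q)
        return b, float(self.y_mean - self.x_mean @ b)


@dataclass
class CVResult:
    """Cross-validation trace over candidate LV counts (1-based)."""

    rmsecv: np.ndarray  # rmsecv[a-1] = pooled held-out RMSE with a LVs
    rcv: np.ndarray
    best_lv: int
    folds: list[np.ndarray]
    seed: int

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_lv - 1])

    @property
    def best_rcv(self) -> float:
        return float(self.rcv[self.best_lv - 1])


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_lv`` latent variables.

    Deterministic.  If a component's weight vector has (near-)zero norm
    the data are exhausted; the model is truncated to the attained number
    of components with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise InvalidParameterError("X and y disagree on sample count")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise InvalidParameterError("X and y must be finite")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise InvalidParameterError(
            f"n_lv must lie in [1, {max_lv}] for {n} samples x {p} variables"
        )

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.linalg.norm(Xc)) * float(np.linalg.norm(yc)), 1.0)

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    attained = 0
    for a in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            warnings.warn(
                f"PLS rank exhausted after {attained} of {n_lv} components",
                stacklevel=2,
            )
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-24 * scale:
            warnings.warn(
                f"PLS rank exhausted after {attained} of {n_lv} components",
                stacklevel=2,
            )
            break
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        attained += 1

    W, P, q = W[:, :attained], P[:, :attained], q[:attained]
    if attained == 0:
        b = np.zeros(p)
        intercept = y_mean
    else:
        b = W @ np.linalg.solve(P.T @ W, q)
        intercept = float(y_mean - x_mean @ b)
    return PLSModel(
        n_lv=attained,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=b,
        intercept=intercept,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Apply the fitted affine map to new rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coefficients.shape[0]:
        raise InvalidParameterError(
            f"X has {X.shape[-1] if X.ndim else 0} columns, model expects "
            f"{model.coefficients.shape[0]}"
        )
    return X @ model.coefficients + model.intercept


def kfold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform shuffle split into ``n_folds`` near-equal folds."""
    if not 2 <= n_folds <= n:
        raise InvalidParameterError(f"need 2 <= n_folds <= n, got {n_folds} / {n}")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), n_folds)]


def select_lv_by_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = MAX_LV_DEFAULT,
    n_folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Choose the LV count minimising the pooled k-fold RMSECV.

    For each candidate LV count the held-out predictions of every fold
    are pooled and scored with the package's RMSE and correlation
    metrics; ties in RMSECV break toward the smaller LV count.
    """
    from .evaluate import correlation, rmse  # local import: evaluate uses pls too

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_lv < 1:
        raise InvalidParameterError("max_lv must be at least 1")
    folds = kfold_indices(n, n_folds, seed)
    min_train = n - max(len(f) for f in folds)
    a_max = min(max_lv, p, min_train - 1)
    if a_max < 1:
        raise InvalidParameterError("too few samples per fold for even one LV")

    pooled = np.zeros((a_max, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank exhaustion within a fold is benign
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            model = fit_pls(X[train], y[train], a_max)
            for a in range(1, a_max + 1):
                b, b0 = model.coefficients_for(min(a, model.n_lv))
                pooled[a - 1, fold] = X[fold] @ b + b0

    from .errors import UndefinedCorrelationError

    def _safe_r(pred: np.ndarray) -> float:
        try:
            return correlation(y, pred)
        except UndefinedCorrelationError:
            return float("nan")  # degenerate fold predictions

    rmsecv = np.array([rmse(y, pooled[a]) for a in range(a_max)])
    rcv = np.array([_safe_r(pooled[a]) for a in range(a_max)])
    best = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest) index
    return CVResult(rmsecv=rmsecv, rcv=rcv, best_lv=best, folds=folds, seed=seed)
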