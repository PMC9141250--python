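"""Effective-wavelength selection: SPA and CARS.

Two canonical selectors reduce the 1497-channel truncated spectrum to a
small subset of informative wavelengths:

* **SPA** (successive projections algorithm): forward selection that, at
  each step, picks the column with the largest norm orthogonal to the
  span of the columns already chosen, minimising collinearity.  Every
  (starting wavelength, chain length) candidate subset is scored by the
  cross-validated RMSE of an ordinary least-squares fit; the minimiser
  wins, ties breaking toward fewer variables, then the lower start index.
* **CARS** (competitive adaptive reweighted sampling): a Monte-Carlo
  elimination loop.  Each run fits PLS on a random subsample of the
  calibration set using the currently retained wavelengths, weights each
  wavelength by its normalised absolute regression coefficient, enforces
  an exponentially decreasing retention ratio (EDF), resamples
  wavelengths with probability proportional to weight (ARS), and records
  the 10-fold RMSECV of the surviving subset.  The subset with the
  smallest RMSECV across runs wins, ties breaking toward the earlier run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .grid import WavelengthGrid
from .pls import fit_pls, kfold_indices, select_lv_by_cv, MAX_LV_DEFAULT

__all__ = [
    "SelectionMethod",
    "SelectionResult",
    "edf_ratio",
    "spa_select",
    "cars_select",
    "refit_with_selection",
]


class SelectionMethod(str, Enum):
    SPA = "SPA"
    CARS = "CARS"


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run."""

    method: SelectionMethod
    selected_indices: np.ndarray  # unique column indices, selection order
    selected_nm: np.ndarray | None
    diagnostics: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if len(np.unique(self.selected_indices)) != self.selected_indices.size:
            raise InvalidParameterError("selected indices must be unique")

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


def edf_ratio(run: int | np.ndarray, n_runs: int, p: int) -> np.ndarray | float:
    """Exponentially decreasing retention ratio of CARS.

    ``r_i = a * exp(-k * i)`` with the two constants fixed by the
    boundary conditions r_1 = 1 (all ``p`` wavelengths survive run 1)
    and r_N = 2/p (only two survive the last run):
    ``k = ln(p/2) / (N - 1)`` and ``a = e^k``.
    """
    if n_runs < 2:
        raise InvalidParameterError("n_runs must be at least 2")
    if p < 2:
        raise InvalidParameterError("p must be at least 2")
    k = math.log(p / 2.0) / (n_runs - 1)
    a = math.exp(k)
    return a * np.exp(-k * np.asarray(run, dtype=float))


def _spa_chains_and_scores(
    X: np.ndarray,
    y: np.ndarray,
    m_min: int,
    m_max: int,
    folds: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """For every starting column build the projection chain of length
    ``m_max`` and score each prefix by pooled CV RMSE of an OLS fit.

    Returns ``chains`` (p, m_max) and ``scores`` (p, m_max) where
    ``scores[s, m-1]`` is the CV RMSE of the chain started at column
    ``s`` truncated to ``m`` variables (NaN below ``m_min``).
    """
    n, p = X.shape
    norm = np.linalg.norm(X, axis=0)
    norm[norm == 0] = 1.0
    Xn = X / norm  # unit columns: projection geometry only
    G = Xn.T @ Xn

    chains = np.zeros((p, m_max), dtype=int)
    scores = np.full((p, m_max), np.nan)

    fold_sets = [(np.setdiff1d(np.arange(n), f), f) for f in folds]

    for start in range(p):
        # Gram-space modified Gram-Schmidt: r2[j] tracks the squared norm
        # of column j orthogonal to the span of the chosen columns.
        r2 = np.ones(p)  # unit columns
        V = np.zeros((m_max, p))
        chain = np.empty(m_max, dtype=int)
        k = start
        for step in range(m_max):
            chain[step] = k
            rk = math.sqrt(max(r2[k], 1e-30))
            v = (G[k] - V[:step, k] @ V[:step]) / rk
            V[step] = v
            r2 = np.maximum(r2 - v * v, 0.0)
            r2[chain[: step + 1]] = -np.inf
            if step + 1 < m_max:
                k = int(np.argmax(r2))
                if r2[k] <= 1e-20:
                    chain[step + 1 :] = chain[step]  # degenerate: repeat, scored as-is
                    break
        chains[start] = chain

        # score prefixes with OLS + intercept via fold-wise Gram prefixes
        sq_err = np.zeros(m_max)
        for train, test in fold_sets:
            A = np.empty((len(train), m_max + 1))
            A[:, 0] = 1.0
            A[:, 1:] = X[np.ix_(train, chain)]
            B = np.empty((len(test), m_max + 1))
            B[:, 0] = 1.0
            B[:, 1:] = X[np.ix_(test, chain)]
            Gf = A.T @ A
            bf = A.T @ y[train]
            for m in range(m_min, m_max + 1):
                try:
                    beta = np.linalg.solve(Gf[: m + 1, : m + 1], bf[: m + 1])
                except np.linalg.LinAlgError:
                    beta = np.linalg.lstsq(
                        Gf[: m + 1, : m + 1], bf[: m + 1], rcond=None
                    )[0]
                resid = y[test] - B[:, : m + 1] @ beta
                sq_err[m - 1] += float(resid @ resid)
        scores[start, m_min - 1 :] = np.sqrt(sq_err[m_min - 1 :] / n)
    return chains, scores


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    m_min: int = 1,
    m_max: int = 25,
    n_folds: int = 10,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Successive projections algorithm over all starting wavelengths.

    Candidate subsets are the projection chains of every start column at
    every length in ``[m_min, m_max]``, scored by ``n_folds``-fold CV
    RMSE of a multiple linear regression (SPA subsets are small and
    decorrelated, so MLR is the standard scorer).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= m_min <= m_max:
        raise InvalidParameterError("need 1 <= m_min <= m_max")
    if m_max >= n:
        raise InvalidParameterError(
            f"m_max={m_max} must be below n_cal={n} (MLR underdetermined)"
        )
    m_max = min(m_max, p)
    m_min = min(m_min, m_max)
    folds = kfold_indices(n, n_folds, seed)
    chains, scores = _spa_chains_and_scores(X, y, m_min, m_max, folds)

    # lexicographic winner: lowest RMSE, then fewer variables, then start
    best = (np.inf, np.inf, np.inf)
    for m in range(m_min, m_max + 1):
        col = scores[:, m - 1]
        s = int(np.nanargmin(col))
        cand = (float(col[s]), m, s)
        if cand < best:
            best = cand
    _, m_best, s_best = best
    idx = np.unique(chains[s_best, : int(m_best)], return_index=True)
    selected = chains[s_best, : int(m_best)][np.sort(idx[1])]
    return SelectionResult(
        method=SelectionMethod.SPA,
        selected_indices=selected,
        selected_nm=None if grid is None else grid.wavelengths[selected],
        diagnostics={
            "cv_rmse": float(best[0]),
            "start_index": int(s_best),
            "n_candidates": int(p * (m_max - m_min + 1)),
            "scores_by_length": {
                int(m): float(np.nanmin(scores[:, m - 1]))
                for m in range(m_min, m_max + 1)
            },
        },
        seed=seed,
    )


def cars_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_runs: int = 50,
    subsample: float = 0.8,
    max_lv: int = MAX_LV_DEFAULT,
    n_folds: int = 10,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    See the module docstring for the loop.  The recorded per-run RMSECV
    uses the full calibration set and the package's CV-based LV choice,
    capped at ``max_lv``.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if n_runs < 2:
        raise InvalidParameterError("n_runs must be at least 2")
    if not 0 < subsample <= 1:
        raise InvalidParameterError("subsample must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sub = max(int(math.ceil(subsample * n)), 2)
    ratios = np.atleast_1d(edf_ratio(np.arange(1, n_runs + 1), n_runs, p))

    retained = np.arange(p)
    trace: list[dict[str, Any]] = []
    best_run = -1
    best_rmsecv = np.inf
    best_subset: np.ndarray | None = None
    best_lv = 1

    for i in range(n_runs):
        if retained.size < 2:
            break
        sub = np.sort(rng.choice(n, size=n_sub, replace=False))
        Xs = X[np.ix_(sub, retained)]
        ys = y[sub]
        cv_sub = select_lv_by_cv(
            Xs, ys, max_lv=min(max_lv, retained.size),
            n_folds=min(n_folds, n_sub), seed=seed + i + 1,
        )
        model = fit_pls(Xs, ys, cv_sub.best_lv)
        w = np.abs(model.coefficients)
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()

        k_keep = min(int(math.ceil(ratios[i] * p)), retained.size)
        top = np.argsort(-w, kind="stable")[:k_keep]  # EDF: forced top-weight cut
        w_top = w[top] / w[top].sum()
        draws = rng.choice(top.size, size=k_keep, replace=True, p=w_top)  # ARS
        keep_local = np.unique(top[draws])
        retained = np.sort(retained[keep_local])
        if retained.size < 2:
            trace.append(
                {"run": i + 1, "n_retained": int(retained.size), "rmsecv": np.nan}
            )
            break

        cv = select_lv_by_cv(
            X[:, retained], y, max_lv=min(max_lv, retained.size), n_folds=n_folds,
            seed=seed,
        )
        trace.append(
            {
                "run": i + 1,
                "n_retained": int(retained.size),
                "rmsecv": cv.best_rmsecv,
                "n_lv": cv.best_lv,
            }
        )
        if cv.best_rmsecv < best_rmsecv:  # strict: ties keep the earlier run
            best_rmsecv = cv.best_rmsecv
            best_run = i + 1
            best_subset = retained.copy()
            best_lv = cv.best_lv

    if best_subset is None:
        raise InvalidParameterError("CARS retained fewer than 2 wavelengths throughout")
    return SelectionResult(
        method=SelectionMethod.CARS,
        selected_indices=best_subset,
        selected_nm=None if grid is None else grid.wavelengths[best_subset],
        diagnostics={
            "best_run": int(best_run),
            "rmsecv": float(best_rmsecv),
            "n_lv": int(best_lv),
            "trace": trace,
        },
        seed=seed,
    )


def refit_with_selection(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    selection: SelectionResult | np.ndarray,
    max_lv: int = MAX_LV_DEFAULT,
    n_folds: int = 10,
    seed: int = 0,
):
    """Re-model on the selected wavelengths and evaluate on both sets.

    Returns ``(row_dict, model, cv_result)`` where ``row_dict`` carries
    the standard metric set (LVs, RCV, RMSECV, RC, RMSEC, RP, RMSEP).
    """
    from .evaluate import correlation, rmse

    idx = (
        selection.selected_indices
        if isinstance(selection, SelectionResult)
        else np.asarray(selection, dtype=int)
    )
    if idx.size == 0:
        raise InvalidParameterError("selection is empty")
    Xc = np.asarray(X_cal, dtype=float)[:, idx]
    Xv = np.asarray(X_val, dtype=float)[:, idx]
    cv = select_lv_by_cv(Xc, y_cal, max_lv=min(max_lv, idx.size), n_folds=n_folds, seed=seed)
    model = fit_pls(Xc, y_cal, cv.best_lv)
    model.wavelength_indices = idx.copy()
    yc_hat = Xc @ model.coefficients + model.intercept
    yv_hat = Xv @ model.coefficients + model.intercept
    row = {
        "n_wavelengths": int(idx.size),
        "n_lv": int(model.n_lv),
        "rcv": cv.best_rcv,
        "rmsecv": cv.best_rmsecv,
        "rc": correlation(y_cal, yc_hat),
        "rmsec": rmse(y_cal, yc_hat),
        "rp": correlation(y_val, yv_hat),
        "rmsep": rmse(y_val, yv_hat),
    }
    return row, model, cv
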