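"""Model evaluation metrics and the orientation x region comparison.

Metrics follow the chemometrics convention: Pearson correlation R
between measured and predicted SSC, and RMSE with divisor n (no
degrees-of-freedom correction), reported in SSC percentage points.
Subscripts distinguish where they are computed: RCV/RMSECV on pooled
cross-validation predictions, RC/RMSEC on the calibration set,
RP/RMSEP on the validation set.

``run_comparison`` reproduces the study design: full-spectrum PLS models
for every (orientation, zone combination) cell, then SPA- and
CARS-reduced models for the best-practice S1--S3 combination in both
orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedCorrelationError
from .preprocess import Combination, SpectraMatrix, preprocess_pipeline
from .pls import MAX_LV_DEFAULT, CVResult, PLSModel, fit_pls, select_lv_by_cv
from .synth import Orientation
from .wavesel import SelectionMethod, SelectionResult, cars_select, spa_select

__all__ = [
    "correlation",
    "rmse",
    "EvaluationRow",
    "EvaluationReport",
    "EvaluationOutcome",
    "evaluate_matrices",
    "evaluate_configuration",
    "run_comparison",
]

REPORT_COLUMNS = [
    "orientation",
    "combination",
    "selector",
    "n_wavelengths",
    "n_lv",
    "rcv",
    "rmsecv",
    "rc",
    "rmsec",
    "rp",
    "rmsep",
]


def correlation(y_measured: np.ndarray, y_predicted: np.ndarray) -> float:
    """Pearson correlation coefficient R between measured and predicted
    values; undefined (error) if either vector is constant."""
    ym = np.asarray(y_measured, dtype=float).ravel()
    yp = np.asarray(y_predicted, dtype=float).ravel()
    if ym.shape != yp.shape or ym.size < 2:
        raise InvalidParameterError("need two equal-length vectors of size >= 2")
    dm = ym - ym.mean()
    dp = yp - yp.mean()
    nm = float(np.sqrt(dm @ dm))
    np_ = float(np.sqrt(dp @ dp))
    if nm == 0 or np_ == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(dm @ dp) / (nm * np_)


def rmse(y_measured: np.ndarray, y_predicted: np.ndarray) -> float:
    """Root-mean-square error with divisor n, in the units of y (% SSC)."""
    ym = np.asarray(y_measured, dtype=float).ravel()
    yp = np.asarray(y_predicted, dtype=float).ravel()
    if ym.size == 0 or ym.shape != yp.shape:
        raise InvalidParameterError("need two equal-length nonempty vectors")
    d = yp - ym
    return float(np.sqrt(d @ d / ym.size))


@dataclass
class EvaluationRow:
    """One model configuration's metric set (a machine-readable analogue
    of a row in a calibration/validation results table)."""

    orientation: str
    combination: str
    selector: str  # "full", "SPA" or "CARS"
    n_wavelengths: int
    n_lv: int
    rcv: float
    rmsecv: float
    rc: float
    rmsec: float
    rp: float
    rmsep: float

    def __post_init__(self) -> None:
        for name in ("rmsecv", "rmsec", "rmsep"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        for name in ("rcv", "rc", "rp"):
            v = getattr(self, name)
            if np.isfinite(v) and abs(v) > 1 + 1e-12:
                raise InvalidParameterError(f"|{name}| must not exceed 1")


@dataclass
class EvaluationReport:
    rows: list[EvaluationRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows], columns=REPORT_COLUMNS)

    def __len__(self) -> int:
        return len(self.rows)

    def best_by_rmsep(self) -> EvaluationRow:
        if not self.rows:
            raise InvalidParameterError("report is empty")
        return min(self.rows, key=lambda r: r.rmsep)


@dataclass
class EvaluationOutcome:
    """Row plus the artifacts behind it."""

    row: EvaluationRow
    model: PLSModel
    cv: CVResult
    selection: SelectionResult | None = None
    matrix: SpectraMatrix | None = None


def evaluate_matrices(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_lv: int = MAX_LV_DEFAULT,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[dict[str, Any], PLSModel, CVResult]:
    """CV-select LVs, fit on calibration, score on both sets."""
    cv = select_lv_by_cv(X_cal, y_cal, max_lv=max_lv, n_folds=n_folds, seed=seed)
    model = fit_pls(X_cal, y_cal, cv.best_lv)
    yc_hat = X_cal @ model.coefficients + model.intercept
    yv_hat = X_val @ model.coefficients + model.intercept
    row = {
        "n_wavelengths": int(X_cal.shape[1]),
        "n_lv": int(model.n_lv),
        "rcv": cv.best_rcv,
        "rmsecv": cv.best_rmsecv,
        "rc": correlation(y_cal, yc_hat),
        "rmsec": rmse(y_cal, yc_hat),
        "rp": correlation(y_val, yv_hat),
        "rmsep": rmse(y_val, yv_hat),
    }
    return row, model, cv


def evaluate_configuration(
    scan_sets: Iterable,
    orientation: Orientation | str,
    combination: Combination | str,
    selector: SelectionMethod | str | None = None,
    config=None,
    seed: int | None = None,
) -> EvaluationOutcome:
    """Run the full chain for one configuration cell.

    Filters the scan sets to one orientation, preprocesses with the
    requested zone combination, optionally reduces wavelengths with SPA
    or CARS on the calibration set, CV-selects the LV count, fits PLS
    and reports metrics on calibration and validation sets.
    """
    from .config import RunConfig

    cfg = config if config is not None else RunConfig()
    if seed is None:
        seed = cfg.seed
    orientation = Orientation(orientation)
    combination = Combination(combination)
    selector = None if selector in (None, "none", "full") else SelectionMethod(selector)

    subset = [fs for fs in scan_sets if Orientation(fs.orientation) is orientation]
    if not subset:
        raise InvalidParameterError(f"no scans for orientation {orientation.value}")
    label = f"{orientation.value}/{combination.value}/{selector.value if selector else 'full'}"
    try:
        mat = preprocess_pipeline(
            subset,
            combination,
            window=cfg.window,
            lo_nm=cfg.lo_nm,
            hi_nm=cfg.hi_nm,
            snv_ddof=cfg.snv_ddof,
        )
        cal = mat.subset("calibration")
        val = mat.subset("validation")
        if cal.n_samples == 0 or val.n_samples == 0:
            raise InvalidParameterError("need both calibration and validation samples")

        selection: SelectionResult | None = None
        if selector is SelectionMethod.SPA:
            selection = spa_select(
                cal.values,
                cal.ssc,
                m_min=cfg.spa_m_min,
                m_max=min(cfg.spa_m_max, cal.n_samples - 1),
                n_folds=cfg.n_folds,
                seed=_derive_seed(seed, 11),
                grid=mat.grid,
            )
        elif selector is SelectionMethod.CARS:
            selection = cars_select(
                cal.values,
                cal.ssc,
                n_runs=cfg.cars_n_runs,
                subsample=cfg.cars_subsample,
                max_lv=cfg.max_lv,
                n_folds=cfg.n_folds,
                seed=_derive_seed(seed, 12),
                grid=mat.grid,
            )

        cv_seed = _derive_seed(seed, 13)
        if selection is not None:
            idx = selection.selected_indices
            Xc, Xv = cal.values[:, idx], val.values[:, idx]
        else:
            Xc, Xv = cal.values, val.values
        metrics, model, cv = evaluate_matrices(
            Xc, cal.ssc, Xv, val.ssc,
            max_lv=min(cfg.max_lv, Xc.shape[1]),
            n_folds=cfg.n_folds,
            seed=cv_seed,
        )
        if selection is not None:
            model.wavelength_indices = selection.selected_indices.copy()
    except (InvalidParameterError, UndefinedCorrelationError) as e:
        raise type(e)(f"configuration {label}: {e}") from e

    row = EvaluationRow(
        orientation=orientation.value,
        combination=combination.value,
        selector=selector.value if selector else "full",
        **metrics,
    )
    return EvaluationOutcome(row=row, model=model, cv=cv, selection=selection, matrix=mat)


def _derive_seed(seed: int, tag: int) -> int:
    """Stable sub-seed so pipeline stages are independently reproducible."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(tag,)).generate_state(1)[0] % (2**31)
    )


def run_comparison(
    scan_sets: Iterable,
    config=None,
    orientations: Sequence[Orientation] = (Orientation.O1, Orientation.O2),
    combinations: Sequence[Combination] = (
        Combination.S1S3,
        Combination.S2,
        Combination.S1S2S3,
    ),
    selectors: Sequence[SelectionMethod] = (SelectionMethod.SPA, SelectionMethod.CARS),
    selection_combination: Combination = Combination.S1S3,
) -> tuple[EvaluationReport, list[EvaluationOutcome]]:
    """The complete comparison study.

    Full-spectrum rows for every orientation x combination cell, then a
    row per wavelength selector on ``selection_combination`` (S1--S3 by
    default, the region with the best full-spectrum performance) in each
    orientation: 6 + 4 = 10 rows at the defaults.
    """
    scan_sets = list(scan_sets)
    report = EvaluationReport()
    outcomes: list[EvaluationOutcome] = []
    for o in orientations:
        for c in combinations:
            out = evaluate_configuration(scan_sets, o, c, None, config)
            report.rows.append(out.row)
            outcomes.append(out)
    for o in orientations:
        for sel in selectors:
            out = evaluate_configuration(scan_sets, o, selection_combination, sel, config)
            report.rows.append(out.row)
            outcomes.append(out)
    return report, outcomes
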