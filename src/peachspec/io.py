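"""On-disk formats.

Everything is plain text, deterministic and diff-friendly:

* **scan table** -- wide CSV, one row per raw scan, columns
  ``sample_id, orientation, scan_index`` followed by one column per
  wavelength (header in nm with 2 decimals; values at full precision);
* **metadata table** -- CSV with ``sample_id, orientation, ssc, set,
  diameter_mm``;
* **model** -- versioned JSON;
* **report** -- CSV with one row per evaluated configuration;
* **selection** -- versioned JSON listing the chosen wavelengths.

Delimiter comma, decimal point, UTF-8, numbers at 17 significant digits
(lossless float64 round-trip); none of this is configurable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    InvalidParameterError,
    UnsupportedFormatError,
)
from .grid import WavelengthGrid
from .pls import PLSModel
from .preprocess import SpectraMatrix
from .synth import FruitScanSet, Orientation
from .evaluate import REPORT_COLUMNS, EvaluationReport, EvaluationRow
from .wavesel import SelectionMethod, SelectionResult

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_matrix",
    "read_matrix",
    "write_model",
    "read_model",
    "write_report",
    "read_report",
    "write_selection",
    "read_selection",
]

MODEL_TAG = "peachspec.model/1"
SELECTION_TAG = "peachspec.selection/1"
FLOAT_FMT = "%.17g"
_META_COLUMNS = ["sample_id", "orientation", "ssc", "set", "diameter_mm"]


def _wl_headers(grid: WavelengthGrid) -> list[str]:
    return [f"{w:.2f}" for w in grid.wavelengths]


def write_dataset(
    scan_sets: list[FruitScanSet], scan_path: str | Path, meta_path: str | Path
) -> None:
    """Write the scan table and the metadata table for a list of fruits."""
    if not scan_sets:
        raise InvalidParameterError("no scan sets to write")
    grid = scan_sets[0].grid
    headers = _wl_headers(grid)
    with open(scan_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,orientation,scan_index," + ",".join(headers) + "\n")
        for fs in scan_sets:
            if fs.grid != grid:
                raise InvalidParameterError("all scan sets must share one grid")
            for i, scan in enumerate(fs.scans):
                vals = ",".join(FLOAT_FMT % v for v in scan)
                fh.write(f"{fs.sample_id},{fs.orientation.value},{i},{vals}\n")
    with open(meta_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_META_COLUMNS) + "\n")
        for fs in scan_sets:
            fh.write(
                f"{fs.sample_id},{fs.orientation.value},"
                f"{FLOAT_FMT % fs.ssc_true},{fs.subset},"
                f"{FLOAT_FMT % fs.diameter_mm}\n"
            )


def read_dataset(scan_path: str | Path, meta_path: str | Path) -> list[FruitScanSet]:
    """Read a dataset back; validates the wavelength grid and the
    one-to-one correspondence between scan and metadata tables."""
    try:
        scans = pd.read_csv(scan_path, float_precision="round_trip")
        meta = pd.read_csv(meta_path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse dataset: {e}") from e

    fixed = {"sample_id", "orientation", "scan_index"}
    wl_cols = [c for c in scans.columns if c not in fixed]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as e:
        raise FormatError(f"non-numeric wavelength header: {e}") from e
    try:
        grid = WavelengthGrid.from_wavelengths(wavelengths, atol=1e-9)
    except InvalidParameterError as e:
        raise FormatError(f"bad wavelength axis: {e}") from e

    if set(meta.columns) < set(_META_COLUMNS):
        raise FormatError(f"metadata must have columns {_META_COLUMNS}")
    meta_keys = set(zip(meta["sample_id"], meta["orientation"]))
    scan_keys = set(zip(scans["sample_id"], scans["orientation"]))
    missing_meta = scan_keys - meta_keys
    if missing_meta:
        sid, o = sorted(missing_meta)[0]
        raise IntegrityError(f"sample {sid}/{o} present in scans but not in metadata")
    missing_scans = meta_keys - scan_keys
    if missing_scans:
        sid, o = sorted(missing_scans)[0]
        raise IntegrityError(f"sample {sid}/{o} present in metadata but has no scans")

    out: list[FruitScanSet] = []
    meta_idx = meta.set_index(["sample_id", "orientation"])
    for (sid, o), group in scans.groupby(["sample_id", "orientation"], sort=False):
        group = group.sort_values("scan_index")
        row = meta_idx.loc[(sid, o)]
        out.append(
            FruitScanSet(
                sample_id=str(sid),
                orientation=Orientation(o),
                ssc_true=float(row["ssc"]),
                diameter_mm=float(row["diameter_mm"]),
                grid=grid,
                scans=group[wl_cols].to_numpy(dtype=float),
                subset=str(row["set"]),
            )
        )
    return out


def write_matrix(matrix: SpectraMatrix, path: str | Path) -> None:
    """Preprocessed spectra matrix as wide CSV."""
    headers = _wl_headers(matrix.grid)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,ssc,set," + ",".join(headers) + "\n")
        for sid, ssc, flag, row in zip(
            matrix.sample_ids, matrix.ssc, matrix.set_flag, matrix.values
        ):
            vals = ",".join(FLOAT_FMT % v for v in row)
            fh.write(f"{sid},{FLOAT_FMT % ssc},{flag},{vals}\n")


def read_matrix(path: str | Path) -> SpectraMatrix:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse matrix: {e}") from e
    wl_cols = [c for c in df.columns if c not in {"sample_id", "ssc", "set"}]
    try:
        grid = WavelengthGrid.from_wavelengths(
            np.array([float(c) for c in wl_cols]), atol=1e-9
        )
    except (ValueError, InvalidParameterError) as e:
        raise FormatError(f"bad wavelength axis: {e}") from e
    return SpectraMatrix(
        sample_ids=[str(s) for s in df["sample_id"]],
        grid=grid,
        values=df[wl_cols].to_numpy(dtype=float),
        ssc=df["ssc"].to_numpy(dtype=float),
        set_flag=df["set"].to_numpy(),
    )


def write_model(model: PLSModel, path: str | Path) -> None:
    """Versioned JSON serialisation of a fitted PLS model."""
    if model.n_lv < 1:
        raise InvalidParameterError("refusing to serialise a model with 0 LVs")
    data = {
        "format": MODEL_TAG,
        "n_lv": int(model.n_lv),
        "x_mean": model.x_mean.tolist(),
        "y_mean": float(model.y_mean),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "intercept": float(model.intercept),
        "wavelength_indices": (
            None
            if model.wavelength_indices is None
            else [int(i) for i in model.wavelength_indices]
        ),
    }
    Path(path).write_text(
        json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_model(path: str | Path) -> PLSModel:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise FormatError(f"cannot parse model file: {e}") from e
    if not isinstance(data, dict) or data.get("format") != MODEL_TAG:
        raise UnsupportedFormatError(
            f"expected model format tag {MODEL_TAG!r}, got {data.get('format')!r}"
            if isinstance(data, dict)
            else "model file is not a JSON object"
        )
    return PLSModel(
        n_lv=int(data["n_lv"]),
        x_mean=np.array(data["x_mean"], dtype=float),
        y_mean=float(data["y_mean"]),
        weights=np.array(data["weights"], dtype=float),
        x_loadings=np.array(data["x_loadings"], dtype=float),
        y_loadings=np.array(data["y_loadings"], dtype=float),
        coefficients=np.array(data["coefficients"], dtype=float),
        intercept=float(data["intercept"]),
        wavelength_indices=(
            None
            if data["wavelength_indices"] is None
            else np.array(data["wavelength_indices"], dtype=int)
        ),
    )


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """One CSV row per evaluated configuration; header always present."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(REPORT_COLUMNS) + "\n")
        for r in report.rows:
            fh.write(
                f"{r.orientation},{r.combination},{r.selector},"
                f"{r.n_wavelengths},{r.n_lv},"
                + ",".join(
                    FLOAT_FMT % getattr(r, k)
                    for k in ("rcv", "rmsecv", "rc", "rmsec", "rp", "rmsep")
                )
                + "\n"
            )


def read_report(path: str | Path) -> EvaluationReport:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse report: {e}") from e
    if list(df.columns) != REPORT_COLUMNS:
        raise FormatError(f"report must have columns {REPORT_COLUMNS}")
    rows = [
        EvaluationRow(
            orientation=str(r.orientation),
            combination=str(r.combination),
            selector=str(r.selector),
            n_wavelengths=int(r.n_wavelengths),
            n_lv=int(r.n_lv),
            rcv=float(r.rcv),
            rmsecv=float(r.rmsecv),
            rc=float(r.rc),
            rmsec=float(r.rmsec),
            rp=float(r.rp),
            rmsep=float(r.rmsep),
        )
        for r in df.itertuples()
    ]
    return EvaluationReport(rows=rows)


def write_selection(selection: SelectionResult, path: str | Path) -> None:
    data = {
        "format": SELECTION_TAG,
        "method": selection.method.value,
        "selected_indices": [int(i) for i in selection.selected_indices],
        "selected_nm": (
            None
            if selection.selected_nm is None
            else [float(v) for v in selection.selected_nm]
        ),
        "seed": int(selection.seed),
        "diagnostics": _jsonable(selection.diagnostics),
    }
    Path(path).write_text(
        json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_selection(path: str | Path) -> SelectionResult:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise FormatError(f"cannot parse selection file: {e}") from e
    if not isinstance(data, dict) or data.get("format") != SELECTION_TAG:
        raise UnsupportedFormatError(f"expected selection format tag {SELECTION_TAG!r}")
    return SelectionResult(
        method=SelectionMethod(data["method"]),
        selected_indices=np.array(data["selected_indices"], dtype=int),
        selected_nm=(
            None if data["selected_nm"] is None else np.array(data["selected_nm"])
        ),
        diagnostics=data.get("diagnostics", {}),
        seed=int(data.get("seed", 0)),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for valid JSON
        return None
    return obj
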