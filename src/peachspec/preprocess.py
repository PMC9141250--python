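"""Spectral preprocessing.

Two preprocessing routes are supported, differing only in which raw scans
of a fruit are averaged before the common chain is applied:

* *whole-fruit route*: average every raw transmittance scan of the fruit
  (this equals the three-zone combination ``S1S2S3``);
* *zone route*: divide the scan sequence into three contiguous,
  approximately equal zones S1 / S2 / S3 along the traversal direction
  (S2 holds the pit) and average the scans of a chosen zone combination.

The common chain is: truncate to 652.25--1026.25 nm, moving-average
smooth (window 9), then standard normal variate (SNV) per spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateSampleError,
    DegenerateSpectrumError,
    InvalidParameterError,
)
from .grid import TRUNCATED_HI_NM, TRUNCATED_LO_NM, WavelengthGrid

__all__ = [
    "Zone",
    "ZoneSplit",
    "Combination",
    "SpectraMatrix",
    "split_scan_counts",
    "combination_mean",
    "truncate",
    "moving_average",
    "snv",
    "preprocess_pipeline",
]


class Zone(str, Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"


class Combination(str, Enum):
    """Which fruit zones contribute scans to the per-fruit mean spectrum."""

    S1S3 = "S1S3"
    S2 = "S2"
    S1S2S3 = "S1S2S3"

    @property
    def zones(self) -> frozenset[Zone]:
        return {
            Combination.S1S3: frozenset({Zone.S1, Zone.S3}),
            Combination.S2: frozenset({Zone.S2}),
            Combination.S1S2S3: frozenset({Zone.S1, Zone.S2, Zone.S3}),
        }[self]


@dataclass(frozen=True)
class ZoneSplit:
    """Counts of raw scans assigned to the three contiguous zones.

    The outer zones take ``ceil(n_raw / 3)`` scans each and the middle
    zone the remainder, so ``n_s1 == n_s3`` and the middle zone is never
    larger than an outer one.
    """

    n_s1: int
    n_s2: int
    n_s3: int

    @property
    def n_raw(self) -> int:
        return self.n_s1 + self.n_s2 + self.n_s3

    def indices(self, zone: Zone) -> np.ndarray:
        """Scan indices (traversal order) belonging to ``zone``."""
        if zone is Zone.S1:
            return np.arange(0, self.n_s1)
        if zone is Zone.S2:
            return np.arange(self.n_s1, self.n_s1 + self.n_s2)
        return np.arange(self.n_s1 + self.n_s2, self.n_raw)

    def combination_indices(self, combination: Combination) -> np.ndarray:
        zones = combination.zones
        if not zones:
            raise InvalidParameterError("combination has no member zones")
        parts = [self.indices(z) for z in (Zone.S1, Zone.S2, Zone.S3) if z in zones]
        return np.concatenate(parts)


def split_scan_counts(n_raw: int) -> ZoneSplit:
    """Three-zone split of ``n_raw`` ordered scans.

    ``n_s1 = n_s3 = ceil(n_raw / 3)``; the middle zone takes what is left.
    Fewer than 5 scans leave the middle (pit) zone empty or negative and
    are rejected as degenerate.
    """
    n_raw = int(n_raw)
    if n_raw < 5:
        raise DegenerateSampleError(
            f"need at least 5 scans for a three-zone split, got {n_raw}"
        )
    n_outer = math.ceil(n_raw / 3)
    return ZoneSplit(n_outer, n_raw - 2 * n_outer, n_outer)


def combination_mean(scan_set, combination: Combination) -> np.ndarray:
    """Unweighted mean spectrum over the scans of the chosen zones.

    ``S1S2S3`` therefore equals the plain mean of all scans, i.e. the
    whole-fruit route's mean spectrum.
    """
    scans = np.asarray(scan_set.scans, dtype=float)
    split = split_scan_counts(scans.shape[0])
    idx = split.combination_indices(combination)
    return scans[idx].mean(axis=0)


def truncate(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    lo_nm: float = TRUNCATED_LO_NM,
    hi_nm: float = TRUNCATED_HI_NM,
) -> tuple[np.ndarray, WavelengthGrid]:
    """Inclusive slice of a spectrum (or a matrix of row spectra) to
    ``[lo_nm, hi_nm]``; both bounds must lie on the grid."""
    values = np.asarray(spectrum, dtype=float)
    if values.shape[-1] != grid.n_points:
        raise InvalidParameterError(
            f"spectrum has {values.shape[-1]} channels, grid has {grid.n_points}"
        )
    i = grid.index_of(lo_nm)
    j = grid.index_of(hi_nm)
    if j <= i:
        raise InvalidParameterError("truncation bounds must satisfy lo < hi")
    return values[..., i : j + 1], grid.truncated(lo_nm, hi_nm)


def moving_average(spectrum: np.ndarray, window: int = 9) -> np.ndarray:
    """Centred moving-average smoother.

    Interior points use the full odd ``window``; near the edges the
    window shrinks symmetrically to the largest centred window that fits,
    so the output has the same length as the input and linear trends pass
    through unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be a positive odd integer")
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    if window > n:
        raise InvalidParameterError(f"window {window} exceeds spectrum length {n}")
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h + 1
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def snv(spectrum: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: per-spectrum ``(T - mean) / sd``.

    ``ddof=1`` (sample standard deviation) is the default convention;
    ``ddof=0`` is available for parity with population-sd variants.
    Constant spectra are rejected rather than mapped to NaN.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 2:
        raise InvalidParameterError("SNV needs at least 2 channels")
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("zero-variance spectrum cannot be SNV-normalised")
    return (x - mu) / sd


@dataclass
class SpectraMatrix:
    """Final per-fruit mean spectra, one row per sample, with aligned
    SSC values and calibration/validation flags."""

    sample_ids: list[str]
    grid: WavelengthGrid
    values: np.ndarray
    ssc: np.ndarray
    set_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, self.grid.n_points):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {self.grid.n_points} channels"
            )
        if self.ssc.shape != (n,):
            raise InvalidParameterError("ssc length must equal sample count")
        if self.set_flag is None:
            self.set_flag = np.array(["calibration"] * n)
        self.set_flag = np.asarray(self.set_flag)
        if np.any(~np.isfinite(self.values)) or np.any(~np.isfinite(self.ssc)):
            raise InvalidParameterError("matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, flag: str) -> "SpectraMatrix":
        mask = self.set_flag == flag
        return SpectraMatrix(
            [s for s, m in zip(self.sample_ids, mask) if m],
            self.grid,
            self.values[mask],
            self.ssc[mask],
            self.set_flag[mask],
        )


def preprocess_pipeline(
    scan_sets: Iterable,
    combination: Combination = Combination.S1S2S3,
    window: int = 9,
    lo_nm: float = TRUNCATED_LO_NM,
    hi_nm: float = TRUNCATED_HI_NM,
    snv_ddof: int = 1,
) -> SpectraMatrix:
    """Full per-fruit chain: combination mean -> truncate -> smooth -> SNV.

    All scan sets must share one wavelength grid.  Errors raised by a
    stage are re-raised annotated with the offending sample id.
    """
    scan_sets = list(scan_sets)
    if not scan_sets:
        raise InvalidParameterError("no scan sets to preprocess")
    grid = scan_sets[0].grid
    rows = []
    out_grid = None
    for fs in scan_sets:
        if fs.grid != grid:
            raise InvalidParameterError(
                f"sample {fs.sample_id} is on a different wavelength grid"
            )
        try:
            mean = combination_mean(fs, combination)
            trunc, out_grid = truncate(mean, grid, lo_nm, hi_nm)
            smooth = moving_average(trunc, window)
            rows.append(snv(smooth, ddof=snv_ddof))
        except (InvalidParameterError, DegenerateSampleError, DegenerateSpectrumError) as e:
            raise type(e)(f"sample {fs.sample_id}: {e}") from e
    return SpectraMatrix(
        [fs.sample_id for fs in scan_sets],
        out_grid,
        np.vstack(rows),
        np.array([fs.ssc_true for fs in scan_sets], dtype=float),
        np.array([fs.subset for fs in scan_sets]),
    )
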