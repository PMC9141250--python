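"""Wavelength grids.

A grid is a closed, evenly spaced wavelength axis in nanometres.  The
acquisition default is 560--1071.75 nm at 0.25 nm steps (2048 channels);
the analysis default truncates it to 652.25--1026.25 nm (1497 channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: absolute tolerance (nm) for deciding whether a wavelength lies on a grid
GRID_ATOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered wavelength axis with a fixed step.

    Parameters
    ----------
    start_nm, stop_nm : float
        First and last wavelength, inclusive on both ends.
    step_nm : float
        Spacing between adjacent channels; ``(stop - start) / step`` must
        be an integer to within :data:`GRID_ATOL`.
    """

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise InvalidParameterError("grid step must be positive")
        if self.stop_nm <= self.start_nm:
            raise InvalidParameterError("grid stop must exceed grid start")
        span = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > GRID_ATOL / self.step_nm:
            raise InvalidParameterError(
                f"grid span {self.start_nm}..{self.stop_nm} is not an integer "
                f"multiple of step {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """The axis as a float array of length :attr:`n_points`."""
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, nm: float) -> int:
        """Channel index of a wavelength; raises if it is off-grid."""
        pos = (nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= self.n_points or abs(pos - idx) * self.step_nm > GRID_ATOL:
            raise InvalidParameterError(f"{nm} nm does not lie on grid {self}")
        return idx

    def contains(self, nm: float) -> bool:
        try:
            self.index_of(nm)
        except InvalidParameterError:
            return False
        return True

    def truncated(self, lo_nm: float, hi_nm: float) -> "WavelengthGrid":
        """Sub-grid from ``lo_nm`` to ``hi_nm`` inclusive (both on-grid)."""
        i = self.index_of(lo_nm)
        j = self.index_of(hi_nm)
        if j <= i:
            raise InvalidParameterError("truncation bounds must satisfy lo < hi")
        return WavelengthGrid(self.wavelengths[i], self.wavelengths[j], self.step_nm)

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray, atol: float = GRID_ATOL) -> "WavelengthGrid":
        """Reconstruct a grid from an explicit axis, validating even spacing."""
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise InvalidParameterError("need at least two wavelengths")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        step = float(np.mean(steps))
        if np.max(np.abs(steps - step)) > atol:
            raise InvalidParameterError("wavelength spacing is not constant")
        return cls(float(w[0]), float(w[-1]), step)


#: acquisition grid of the transmittance scanner
FULL_GRID = WavelengthGrid(560.0, 1071.75, 0.25)
#: analysis grid retained after truncation
TRUNCATED_LO_NM = 652.25
TRUNCATED_HI_NM = 1026.25
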