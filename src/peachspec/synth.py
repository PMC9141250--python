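"""Synthetic full-transmittance spectra of peach fruit.

No public raw dataset exists for this analysis, so the package ships a
generator that emulates the statistical structure the pipeline assumes:

* a fruit on a conveyor belt (480 mm/s) is scanned every 5 ms, so the
  number of raw transmittance scans grows with fruit diameter;
* each scan follows a log10 Beer--Lambert law: absorbance is a smooth
  baseline plus Gaussian sugar bands (second/third O-H and C-H overtone
  region, 840--930 nm) whose amplitude is proportional to the fruit's
  soluble-solids content (SSC), plus fixed water bands near 760 and
  970 nm;
* scans traversing the middle third of the fruit cross the pit: their
  sugar signal is attenuated and their baseline (scattering) raised;
* the second scanning orientation (stem--calyx axis horizontal) has a
  longer effective path length and a more pronounced 760 nm band;
* every scan carries a multiplicative (log-normal) scatter factor and
  additive detector noise in transmittance units.

SSC ground truth is drawn from a truncated normal matched to the field
study this emulates (mean 10.70 %, sd 1.54 %, range 7.40--14.50 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .grid import WavelengthGrid
from .preprocess import split_scan_counts

__all__ = [
    "Orientation",
    "Band",
    "BandTable",
    "SynthConfig",
    "FruitScanSet",
    "n_scans_for_diameter",
    "draw_ssc",
    "generate_fruit",
    "generate_dataset",
]


class Orientation(str, Enum):
    """Fruit pose during scanning: stem--calyx axis vertical (O1) or
    horizontal (O2)."""

    O1 = "O1"
    O2 = "O2"


@dataclass(frozen=True)
class Band:
    """A Gaussian absorbance band: centre (nm), width sigma (nm),
    peak amplitude (absorbance units; for sugar bands, per % SSC)."""

    center_nm: float
    sigma_nm: float
    amplitude: float

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.sigma_nm) ** 2
        )


@dataclass(frozen=True)
class BandTable:
    """Spectral model of the fruit flesh.

    ``sugar_bands`` amplitudes are absorbance per % SSC; ``water_bands``
    are fixed.  ``baseline_intercept`` / ``baseline_slope_per_nm`` give a
    smooth linear scattering baseline; ``o2_760_boost`` is the extra
    760 nm band amplitude seen in the horizontal orientation.
    """

    sugar_bands: tuple[Band, ...] = (
        Band(910.0, 25.0, 0.035),
        Band(840.0, 30.0, 0.025),
    )
    water_bands: tuple[Band, ...] = (
        Band(760.0, 15.0, 0.50),
        Band(970.0, 30.0, 0.60),
    )
    baseline_intercept: float = 0.90
    baseline_slope_per_nm: float = 5e-4
    o2_760_boost: float = 0.15

    def sugar_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Absorbance per % SSC across the axis."""
        return sum(b.profile(wavelengths) for b in self.sugar_bands)

    def water_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return sum(b.profile(wavelengths) for b in self.water_bands)

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.baseline_intercept + self.baseline_slope_per_nm * (
            wavelengths - wavelengths[0]
        )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults reproduce the emulated study design
    (150 fruit, 100/50 calibration/validation split, SSC ~ truncated
    N(10.70, 1.54^2) on [7.40, 14.50] %)."""

    n_fruit: int = 150
    ssc_mean: float = 10.70
    ssc_std: float = 1.54
    ssc_min: float = 7.40
    ssc_max: float = 14.50
    diameter_mean_mm: float = 75.0
    diameter_std_mm: float = 5.0
    belt_speed_mm_s: float = 480.0
    scan_interval_s: float = 0.005
    grid_start_nm: float = 560.0
    grid_stop_nm: float = 1071.75
    grid_step_nm: float = 0.25
    pit_signal_attenuation: float = 0.6
    pit_scatter_boost: float = 0.2
    pit_variability: float = 0.10
    orientation_pathlength_ratio: float = 1.15
    ssc_response_sd: float = 0.05
    scatter_sigma: float = 0.10
    noise_sd: float = 2e-4
    reference_intensity: float = 1.0
    n_calibration: int = 100
    n_validation: int = 50
    seed: int = 0
    bands: BandTable = field(default_factory=BandTable)

    def __post_init__(self) -> None:
        if not (self.ssc_min < self.ssc_mean < self.ssc_max):
            raise InvalidParameterError("need ssc_min < ssc_mean < ssc_max")
        if self.ssc_std <= 0 or self.diameter_std_mm <= 0:
            raise InvalidParameterError("standard deviations must be positive")
        if self.n_fruit < 1:
            raise InvalidParameterError("n_fruit must be at least 1")
        if not 0 <= self.pit_signal_attenuation <= 1:
            raise InvalidParameterError("pit_signal_attenuation must lie in [0, 1]")
        if self.pit_scatter_boost < 0:
            raise InvalidParameterError("pit_scatter_boost must be nonnegative")
        if self.orientation_pathlength_ratio <= 0:
            raise InvalidParameterError("orientation_pathlength_ratio must be positive")
        if self.noise_sd < 0 or self.scatter_sigma < 0:
            raise InvalidParameterError("noise_sd and scatter_sigma must be nonnegative")
        if self.pit_variability < 0 or self.ssc_response_sd < 0:
            raise InvalidParameterError(
                "pit_variability and ssc_response_sd must be nonnegative"
            )
        if self.belt_speed_mm_s <= 0 or self.scan_interval_s <= 0:
            raise InvalidParameterError("belt speed and scan interval must be positive")
        self.grid  # validates the wavelength axis

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.grid_start_nm, self.grid_stop_nm, self.grid_step_nm)

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class FruitScanSet:
    """All raw transmittance scans of one fruit in one orientation.

    Scans are ordered front-to-back along the belt traversal; every scan
    lies on ``grid`` and is nonnegative.
    """

    sample_id: str
    orientation: Orientation
    ssc_true: float
    diameter_mm: float
    grid: WavelengthGrid
    scans: np.ndarray
    subset: str = "calibration"

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        self.orientation = Orientation(self.orientation)
        if self.scans.ndim != 2 or self.scans.shape[1] != self.grid.n_points:
            raise InvalidParameterError(
                f"scans must be (n_scans, {self.grid.n_points}), got {self.scans.shape}"
            )
        if self.scans.shape[0] < 5:
            raise InvalidParameterError("a fruit needs at least 5 scans")
        if np.any(self.scans < 0):
            raise InvalidParameterError("transmittance must be nonnegative")

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]


def n_scans_for_diameter(
    diameter_mm: float, belt_speed_mm_s: float = 480.0, scan_interval_s: float = 0.005
) -> int:
    """Number of raw scans recorded while a fruit of the given diameter
    passes the detector: ``round(diameter / (speed * interval))``.

    The spatial spacing between consecutive scans is
    ``speed * interval`` (2.4 mm at the defaults).
    """
    if diameter_mm <= 0 or belt_speed_mm_s <= 0 or scan_interval_s <= 0:
        raise InvalidParameterError("all geometry parameters must be positive")
    return max(int(round(diameter_mm / (belt_speed_mm_s * scan_interval_s))), 1)


def draw_ssc(config: SynthConfig, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw SSC ground truth from the configured truncated normal."""
    a = (config.ssc_min - config.ssc_mean) / config.ssc_std
    b = (config.ssc_max - config.ssc_mean) / config.ssc_std
    return stats.truncnorm.rvs(
        a, b, loc=config.ssc_mean, scale=config.ssc_std, size=n, random_state=rng
    )


def truncated_ssc_mean(config: SynthConfig) -> float:
    """Exact mean of the truncated SSC distribution."""
    a = (config.ssc_min - config.ssc_mean) / config.ssc_std
    b = (config.ssc_max - config.ssc_mean) / config.ssc_std
    return float(stats.truncnorm.mean(a, b, loc=config.ssc_mean, scale=config.ssc_std))


@dataclass(frozen=True)
class FruitEffects:
    """Per-fruit biological nuisance terms, identical across orientations.

    ``response`` scales the absorbance-per-%-SSC (flesh structure and
    temperature shift the sugar-band response between fruits -- the main
    source of irreducible prediction error); ``pit_attenuation`` and
    ``pit_boost`` are this fruit's realised pit-zone effects (pit size
    and position vary, which is what makes the middle zone carry less
    SSC information rather than merely a rescaled copy of it).
    """

    response: float = 1.0
    pit_attenuation: float = 0.0
    pit_boost: float = 0.0

    @classmethod
    def draw(cls, config: SynthConfig, rng: np.random.Generator) -> "FruitEffects":
        g = max(float(rng.normal(1.0, config.ssc_response_sd)), 0.0)
        z1, z2 = rng.normal(size=2)
        att = float(
            np.clip(
                config.pit_signal_attenuation * (1.0 + config.pit_variability * z1),
                0.0,
                1.0,
            )
        )
        boost = config.pit_scatter_boost * max(1.0 + config.pit_variability * z2, 0.0)
        return cls(response=g, pit_attenuation=att, pit_boost=boost)


def scan_absorbance(
    config: SynthConfig,
    ssc_true: float,
    orientation: Orientation,
    in_pit_zone: bool,
    effects: FruitEffects | None = None,
    diameter_mm: float | None = None,
) -> np.ndarray:
    """Noise- and scatter-free absorbance of a single scan.

    Path length scales with fruit diameter; orientation O2 additionally
    scales it by ``orientation_pathlength_ratio`` and deepens the 760 nm
    water band.
    """
    if effects is None:
        effects = FruitEffects(
            pit_attenuation=config.pit_signal_attenuation,
            pit_boost=config.pit_scatter_boost,
        )
    bands = config.bands
    wl = config.grid.wavelengths
    sugar_amp = ssc_true * effects.response
    if in_pit_zone:
        sugar_amp *= 1.0 - effects.pit_attenuation
    a = bands.baseline(wl) + sugar_amp * bands.sugar_profile(wl) + bands.water_profile(wl)
    if in_pit_zone:
        a = a + effects.pit_boost
    path = 1.0 if diameter_mm is None else diameter_mm / config.diameter_mean_mm
    if Orientation(orientation) is Orientation.O2:
        path *= config.orientation_pathlength_ratio
        a = a + Band(760.0, 15.0, bands.o2_760_boost).profile(wl)
    return a * path


def generate_fruit(
    config: SynthConfig,
    sample_id: str,
    orientation: Orientation,
    rng: np.random.Generator,
    ssc_true: float | None = None,
    diameter_mm: float | None = None,
    effects: FruitEffects | None = None,
) -> FruitScanSet:
    """Generate one fruit's raw scan sequence.

    SSC, diameter and the per-fruit effects may be supplied (e.g. to
    scan the same fruit in both orientations); otherwise they are drawn
    from the config's distributions.  Scans in the middle third of the
    traversal carry the pit-zone attenuation and scatter boost.
    """
    if ssc_true is None:
        ssc_true = float(draw_ssc(config, rng, 1)[0])
    if diameter_mm is None:
        diameter_mm = float(
            np.clip(
                rng.normal(config.diameter_mean_mm, config.diameter_std_mm),
                5 * config.belt_speed_mm_s * config.scan_interval_s,
                None,
            )
        )
    if effects is None:
        effects = FruitEffects.draw(config, rng)
    n_raw = n_scans_for_diameter(
        diameter_mm, config.belt_speed_mm_s, config.scan_interval_s
    )
    split = split_scan_counts(n_raw)
    pit = np.zeros(n_raw, dtype=bool)
    pit[split.n_s1 : split.n_s1 + split.n_s2] = True

    a_outer = scan_absorbance(config, ssc_true, orientation, False, effects, diameter_mm)
    a_pit = scan_absorbance(config, ssc_true, orientation, True, effects, diameter_mm)
    absorbance = np.where(pit[:, None], a_pit[None, :], a_outer[None, :])

    scatter = np.exp(rng.normal(0.0, config.scatter_sigma, size=n_raw))
    t = config.reference_intensity * 10.0 ** (-absorbance) * scatter[:, None]
    if config.noise_sd > 0:
        t = t + rng.normal(0.0, config.noise_sd, size=t.shape)
    t = np.clip(t, 0.0, None)
    return FruitScanSet(
        sample_id=sample_id,
        orientation=Orientation(orientation),
        ssc_true=ssc_true,
        diameter_mm=diameter_mm,
        grid=config.grid,
        scans=t,
    )


def generate_dataset(
    config: SynthConfig,
    orientations: Sequence[Orientation] = (Orientation.O1, Orientation.O2),
) -> list[FruitScanSet]:
    """Generate the full study dataset.

    Each of ``config.n_fruit`` fruits is scanned once per requested
    orientation with identical SSC and diameter, then assigned to the
    calibration or validation set by a seeded random split
    (``n_calibration`` / ``n_validation``).  Fully deterministic for a
    fixed config.
    """
    if config.n_calibration + config.n_validation > config.n_fruit:
        raise InvalidParameterError(
            f"split {config.n_calibration}+{config.n_validation} exceeds "
            f"n_fruit={config.n_fruit}"
        )
    ss = np.random.SeedSequence(config.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    order = split_rng.permutation(config.n_fruit)
    flags = np.array(["unused"] * config.n_fruit, dtype=object)
    flags[order[: config.n_calibration]] = "calibration"
    flags[order[config.n_calibration : config.n_calibration + config.n_validation]] = (
        "validation"
    )

    width = max(3, len(str(config.n_fruit)))
    out: list[FruitScanSet] = []
    for i in range(config.n_fruit):
        fruit_ss = np.random.SeedSequence(config.seed, spawn_key=(1, i))
        rng = np.random.default_rng(fruit_ss)
        ssc = float(draw_ssc(config, rng, 1)[0])
        diameter = float(
            np.clip(
                rng.normal(config.diameter_mean_mm, config.diameter_std_mm),
                5 * config.belt_speed_mm_s * config.scan_interval_s,
                None,
            )
        )
        effects = FruitEffects.draw(config, rng)
        for orientation in orientations:
            fs = generate_fruit(
                config,
                sample_id=f"F{i + 1:0{width}d}",
                orientation=orientation,
                rng=rng,
                ssc_true=ssc,
                diameter_mm=diameter,
                effects=effects,
            )
            fs.subset = str(flags[i])
            out.append(fs)
    return out
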