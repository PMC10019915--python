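"""Relative shallow-marine shelf area through time.

Two routes to the same quantity, the relative flooded-shelf area raised to
the species-area exponent alpha:

1. From a eustatic sea-level curve via the linearized hypsometric
   relation A = k * sigma (k = 2.02e8 km^2 per km of sea-level rise), so
   (A/A0)^alpha = (sigma/sigma0)^alpha with sigma measured above the
   zero-area datum.  Exxon/Haq-style curves overstate amplitudes by about
   a factor of two and can be rescaled before use.
2. From fractional-area series extracted from paleogeographic maps,
   normalized to the youngest value.

Sea level is stored relative to the present-day datum; the conversion to
height above the zero-area datum adds sigma0 = A0 / k, where A0 is the
present-day shallow-marine area (default 2.7e7 km^2, giving sigma0 of
about 134 m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .occurrences import ConfigurationError

logger = logging.getLogger(__name__)

#: Hypsometric gradient, km^2 of shelf gained per km of sea-level rise.
HYPSOMETRIC_K = 2.02e8
#: Present-day shallow-marine area, km^2 (configurable).
DEFAULT_A0 = 2.7e7
#: Default species-area exponent (inter-province regime).
DEFAULT_ALPHA = 0.8
#: Relative areas are clipped below this floor to keep the later
#: area-normalization of diversity finite; every clip is logged.
REL_AREA_FLOOR = 0.05


def sigma0_from_area(a0: float = DEFAULT_A0, k: float = HYPSOMETRIC_K
                     ) -> float:
    """Present sea level above the zero-area datum, in meters."""
    return a0 / k * 1000.0


@dataclass
class SeaLevelCurve:
    """Eustatic sea level vs age, meters relative to the present datum."""

    ages: np.ndarray
    level_m: np.ndarray
    amplitude_factor: float = 1.0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.level_m = np.asarray(self.level_m, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.level_m.shape:
            raise ConfigurationError("sea-level curve: shape mismatch")
        if not np.all(np.diff(self.ages) > 0):
            raise ConfigurationError(
                "sea-level curve: ages must be strictly increasing")
        if not (np.all(np.isfinite(self.ages))
                and np.all(np.isfinite(self.level_m))):
            raise ConfigurationError("sea-level curve: non-finite values")

    @classmethod
    def from_csv(cls, path) -> "SeaLevelCurve":
        df = pd.read_csv(path).sort_values("age_Ma")
        return cls(df["age_Ma"].to_numpy(), df["level_m"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_Ma": self.ages, "level_m": self.level_m}
                     ).to_csv(path, index=False)

    def resampled(self, grid) -> "SeaLevelCurve":
        grid = np.asarray(grid, dtype=float)
        return SeaLevelCurve(grid, _interp(grid, self.ages, self.level_m),
                             self.amplitude_factor)


@dataclass
class AreaCurve:
    """Relative shallow-marine area (A/A0)^alpha on an age grid.

    ``base`` is the alpha=1 ratio A/A0; ``rel_area`` applies the recorded
    exponent.  ``with_alpha`` re-exponentiates without reloading.
    """

    ages: np.ndarray
    base: np.ndarray
    alpha: float = DEFAULT_ALPHA
    region: str = "global"
    source: str = "sealevel"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        if np.any(self.base <= 0):
            raise ConfigurationError("area curve: non-positive relative area")

    @property
    def rel_area(self) -> np.ndarray:
        return self.base ** self.alpha

    def with_alpha(self, alpha: float) -> "AreaCurve":
        return replace(self, alpha=alpha)

    def resampled(self, grid) -> "AreaCurve":
        grid = np.asarray(grid, dtype=float)
        return replace(self, ages=grid,
                       base=_interp(grid, self.ages, self.base))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "age_Ma": self.ages, "rel_area": self.rel_area,
            "alpha": self.alpha, "region": self.region, "source": self.source,
        }).to_csv(path, index=False)


def rescale_amplitude(curve: SeaLevelCurve, factor: float = 0.5
                      ) -> SeaLevelCurve:
    """Rescale sea-level amplitudes (default 0.5, the factor-2 correction
    applied to Exxon/Haq-style curves)."""
    if not factor > 0:
        raise ConfigurationError("amplitude factor must be > 0")
    return SeaLevelCurve(curve.ages, curve.level_m * factor,
                         curve.amplitude_factor * factor)


def hypsometric_area(level_m, k: float = HYPSOMETRIC_K,
                     floor_km2: float = 0.0):
    """Shelf area (km^2) from sea level above the zero-area datum.

    A = k * level, with level converted from meters to km.  Levels below
    the datum would give negative area; they are clipped to ``floor_km2``
    and logged.
    """
    level_m = np.asarray(level_m, dtype=float)
    area = k * level_m / 1000.0
    n_neg = int(np.count_nonzero(area < floor_km2))
    if n_neg:
        logger.warning("hypsometric_area: %d level(s) below the zero-area "
                       "datum clipped to %g km^2", n_neg, floor_km2)
        area = np.maximum(area, floor_km2)
    return area if area.ndim else float(area)


def relative_area(curve: SeaLevelCurve, sigma0: float | None = None,
                  alpha: float = DEFAULT_ALPHA, region: str = "global",
                  level_is_relative: bool = True,
                  floor: float = REL_AREA_FLOOR) -> AreaCurve:
    """Relative shelf area (sigma/sigma0)^alpha from a sea-level curve.

    Parameters
    ----------
    sigma0 : float, optional
        Present sea level above the zero-area datum, meters; defaults to
        A0/k (about 134 m).
    level_is_relative : bool
        If True (default) the curve's levels are relative to present and
        sigma(t) = level(t) + sigma0; if False the levels are already
        heights above the zero-area datum.
    floor : float
        Base ratios at or below this floor are clipped (logged).
    """
    if sigma0 is None:
        sigma0 = sigma0_from_area()
    if not sigma0 > 0:
        raise ConfigurationError("sigma0 must be > 0")
    sigma = curve.level_m + sigma0 if level_is_relative else curve.level_m
    base = sigma / sigma0
    n_clip = int(np.count_nonzero(base <= floor))
    if n_clip:
        logger.warning("relative_area: %d point(s) at or below the %.2g "
                       "floor clipped", n_clip, floor)
        base = np.maximum(base, floor)
    return AreaCurve(curve.ages, base, alpha=alpha, region=region,
                     source="sealevel")


def load_fractional_area(path, region: str = "global",
                         alpha: float = DEFAULT_ALPHA) -> AreaCurve:
    """Load a fractional shallow-marine-area series (map extraction).

    CSV columns ``age_Ma, fraction`` (an optional ``region`` column is
    filtered on).  The base ratio is fraction / fraction at the youngest
    age, so the youngest point defines A0.
    """
    df = pd.read_csv(path)
    if "region" in df.columns:
        df = df[df["region"] == region]
        if df.empty:
            raise ConfigurationError(
                f"no rows for region {region!r} in {path}")
    df = df.sort_values("age_Ma")
    frac = df["fraction"].to_numpy(float)
    if np.any(frac <= 0):
        raise ConfigurationError("fractional area must be positive")
    return AreaCurve(df["age_Ma"].to_numpy(float), frac / frac[0],
                     alpha=alpha, region=region, source="maps")


def _interp(grid: np.ndarray, ages: np.ndarray, values: np.ndarray
            ) -> np.ndarray:
    """Linear interpolation on age; endpoint values held outside support."""
    lo, hi = ages[0], ages[-1]
    n_out = int(np.count_nonzero((grid < lo - 1e-9) | (grid > hi + 1e-9)))
    if n_out:
        logger.warning("resample: %d grid point(s) outside [%g, %g] Ma; "
                       "endpoint values held", n_out, lo, hi)
    return np.interp(grid, ages, values)


def resample_curve(curve, grid):
    """Resample any time-series curve object (with ``.resampled``) or an
    (ages, values) pair onto a new age grid by linear interpolation."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("resample_curve: empty grid")
    if hasattr(curve, "resampled"):
        return curve.resampled(grid)
    ages, values = curve
    return grid, _interp(grid, np.asarray(ages, float),
                         np.asarray(values, float))
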