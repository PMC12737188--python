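"""UV-Vis utilities for gold quantification.

Covers background subtraction of the undoped-carrier spectrum, reading the
surface-plasmon-resonance absorbance near 518 nm, a linear OD-vs-
concentration calibration, and the direct/indirect loading-efficiency
formulas:

    LE_indirect % = (total − free) / total × 100
    LE_direct %   = encapsulated / total × 100

Both refuse mass-balance violations (free or encapsulated exceeding total)
rather than returning out-of-range percentages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ConfigError, DataError

__all__ = [
    "Spectrum",
    "CalibrationCurve",
    "LoadingResult",
    "subtract_background",
    "peak_absorbance",
    "fit_calibration",
    "loading_efficiency_indirect",
    "loading_efficiency_direct",
]


@dataclass
class Spectrum:
    """Absorbance spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise DataError("wavelengths and absorbance must be matching 1D arrays")
        if self.wavelengths.size < 2:
            raise DataError("spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DataError("wavelengths must be strictly increasing")
        if not (
            np.all(np.isfinite(self.wavelengths)) and np.all(np.isfinite(self.absorbance))
        ):
            raise DataError("spectrum contains non-finite values")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "Spectrum":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise DataError(f"spectrum CSV {path} needs two columns")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | os.PathLike) -> str:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "absorbance": self.absorbance}
        ).to_csv(os.fspath(path), index=False, float_format="%.12g")
        return os.fspath(path)


@dataclass
class CalibrationCurve:
    """OLS line OD = slope·c + intercept at a fixed detection wavelength."""

    slope: float
    intercept: float
    r_squared: float
    wavelength: float = 518.0
    max_concentration: float = 0.0

    def quantify(self, od: float) -> float:
        """Invert the line; refuses extrapolation > 110% of calibrated max."""
        if self.slope == 0:
            raise DataError("cannot invert a flat calibration")
        c = (od - self.intercept) / self.slope
        if c < 0:
            raise DataError(f"absorbance {od} maps to negative concentration")
        if self.max_concentration and c > 1.10 * self.max_concentration:
            raise DataError(
                f"concentration {c:.4g} beyond 110% of calibrated range "
                f"({self.max_concentration:.4g})"
            )
        return c


@dataclass
class LoadingResult:
    total_au: float
    free_au: float | None
    encapsulated_au: float | None
    le_percent: float
    method: str  # "indirect" or "direct"


def subtract_background(doped: Spectrum, undoped: Spectrum) -> Spectrum:
    """Pointwise doped − undoped; grids must match exactly (no interpolation).

    Negative differences are preserved, not clipped.
    """
    if doped.wavelengths.shape != undoped.wavelengths.shape or not np.array_equal(
        doped.wavelengths, undoped.wavelengths
    ):
        raise DataError("wavelength grids differ; cannot subtract")
    return Spectrum(doped.wavelengths.copy(), doped.absorbance - undoped.absorbance)


def peak_absorbance(
    spectrum: Spectrum, wavelength: float = 518.0, window: float = 10.0
) -> float:
    """Maximum absorbance within ±window/2 of the target wavelength."""
    if window <= 0:
        raise ConfigError("window must be > 0")
    lo, hi = wavelength - window / 2.0, wavelength + window / 2.0
    if hi < spectrum.wavelengths[0] or lo > spectrum.wavelengths[-1]:
        raise DataError(
            f"window [{lo}, {hi}] nm outside spectrum range "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm"
        )
    sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not sel.any():
        raise DataError("no sample points inside the peak window")
    return float(spectrum.absorbance[sel].max())


def fit_calibration(
    concentrations, absorbances, wavelength: float = 518.0, through_origin: bool = False
) -> CalibrationCurve:
    """Least-squares absorbance-vs-concentration line (free intercept by
    default; set ``through_origin`` to force it to zero)."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise DataError("concentrations and absorbances must be paired 1D")
    if c.size < 3:
        raise DataError("calibration needs at least 3 points")
    if np.unique(c).size < 2:
        raise DataError("calibration needs at least 2 distinct concentrations")
    if through_origin:
        slope = float(np.dot(c, a) / np.dot(c, c))
        intercept = 0.0
        pred = slope * c
        ss_res = float(np.sum((a - pred) ** 2))
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = sps.linregress(c, a)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        wavelength=wavelength,
        max_concentration=float(c.max()),
    )


def loading_efficiency_indirect(total_au: float, free_au: float) -> LoadingResult:
    """LE% from supplied gold minus unencapsulated gold in the supernatant."""
    if total_au <= 0:
        raise DataError("total gold mass must be > 0")
    if free_au < 0:
        raise DataError("free gold mass must be >= 0")
    if free_au > total_au:
        raise DataError(
            f"mass balance violated: free ({free_au}) exceeds total ({total_au})"
        )
    le = 100.0 * (total_au - free_au) / total_au
    return LoadingResult(
        total_au=total_au,
        free_au=free_au,
        encapsulated_au=None,
        le_percent=le,
        method="indirect",
    )


def loading_efficiency_direct(encapsulated_au: float, total_au: float) -> LoadingResult:
    """LE% from directly measured encapsulated gold."""
    if total_au <= 0:
        raise DataError("total gold mass must be > 0")
    if encapsulated_au < 0:
        raise DataError("encapsulated gold mass must be >= 0")
    if encapsulated_au > total_au:
        raise DataError(
            f"mass balance violated: encapsulated ({encapsulated_au}) exceeds "
            f"total ({total_au})"
        )
    le = 100.0 * encapsulated_au / total_au
    return LoadingResult(
        total_au=total_au,
        free_au=None,
        encapsulated_au=encapsulated_au,
        le_percent=le,
        method="direct",
    )
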