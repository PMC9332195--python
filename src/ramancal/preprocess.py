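"""Spectral preprocessing: Savitzky-Golay first derivative, then SNV.

The chain applied before any model fitting is a first derivative computed by
Savitzky-Golay local least-squares fitting (2nd-order polynomial, 31-point
window by default) followed by standard normal variate (SNV) normalization of
each spectrum.  The derivative removes additive baseline offsets and
suppresses smooth fluorescence drift; SNV removes the per-spectrum
multiplicative scatter factor by centering each spectrum and scaling it to
unit standard deviation.

Conventions
-----------
* The derivative is taken with respect to wavenumber (divided by the grid
  increment), so results do not depend on the grid spacing chosen.
* Edges are trimmed to the interior points where the full window fits:
  (window - 1) / 2 channels are dropped at each end (1034 -> 1004 channels on
  the default grid).
* SNV uses the sample standard deviation (n - 1 denominator).

Every preprocessed :class:`~ramancal.io.SpectraSet` carries a fingerprint
hashing the configuration and resulting grid, so that a calibration model can
later refuse spectra prepared differently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectraSet, Spectrum


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the derivative + SNV chain.

    ``sg_window`` must be odd and larger than ``sg_polyorder``; the derivative
    order is fixed at 1 and must not exceed the polynomial order.  ``sd_floor``
    is the tolerance below which SNV refuses a (near-)constant spectrum.
    """

    sg_window: int = 31
    sg_polyorder: int = 2
    sg_deriv: int = 1
    snv: bool = True
    sd_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                "SG window must be odd and greater than the polynomial order"
            )
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("derivative order must not exceed the polynomial order")
        if self.sd_floor < 0:
            raise ValueError("sd_floor must be non-negative")

    @property
    def half_window(self) -> int:
        return (self.sg_window - 1) // 2

    def fingerprint(self, grid: np.ndarray) -> str:
        """Short hash identifying this configuration and the resulting grid."""
        grid = np.asarray(grid, dtype=float)
        payload = {
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "snv": self.snv,
            "grid_first": float(grid[0]),
            "grid_last": float(grid[-1]),
            "grid_len": int(grid.size),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "snv": self.snv,
            "sd_floor": self.sd_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def _uniform_step(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if d.size == 0:
        raise ValueError("grid too short")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
        raise ValueError("Savitzky-Golay filtering requires a uniform grid")
    return float(d[0])


def savgol_first_derivative(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Savitzky-Golay first derivative of one spectrum (per cm^-1).

    Each retained value is the analytic derivative of the local least-squares
    polynomial fit; the output grid is trimmed to the interior points where
    the full window fits.
    """
    step = _uniform_step(spectrum.wavenumbers)
    if len(spectrum) < config.sg_window:
        raise ValueError(
            f"spectrum '{spectrum.sample_id}' has {len(spectrum)} points, "
            f"fewer than the {config.sg_window}-point SG window"
        )
    deriv = savgol_filter(
        spectrum.intensities,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.sg_deriv,
        delta=step,
    )
    h = config.half_window
    return Spectrum(
        spectrum.wavenumbers[h:-h],
        deriv[h:-h],
        sample_id=spectrum.sample_id,
        batch_id=spectrum.batch_id,
        site_id=spectrum.site_id,
        instrument_id=spectrum.instrument_id,
        time_h=spectrum.time_h,
    )


def snv_values(values: np.ndarray, sd_floor: float = 1e-12, label: str = "") -> np.ndarray:
    """SNV-normalize one intensity vector: (x - mean) / sd, sample sd (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SNV requires at least two channels")
    sd = float(np.std(x, ddof=1))
    if sd <= sd_floor:
        raise ValueError(
            f"SNV: spectrum {label or '<unnamed>'} has standard deviation "
            f"{sd:g} at or below the floor {sd_floor:g}"
        )
    return (x - x.mean()) / sd


def snv(spectrum: Spectrum, sd_floor: float = 1e-12) -> Spectrum:
    """SNV-normalize one spectrum (mean 0, unit sample SD)."""
    return Spectrum(
        spectrum.wavenumbers.copy(),
        snv_values(spectrum.intensities, sd_floor, label=spectrum.sample_id),
        sample_id=spectrum.sample_id,
        batch_id=spectrum.batch_id,
        site_id=spectrum.site_id,
        instrument_id=spectrum.instrument_id,
        time_h=spectrum.time_h,
    )


def preprocess_set(
    sset: SpectraSet, config: PreprocessConfig = PreprocessConfig()
) -> SpectraSet:
    """Apply SG first derivative then (optionally) SNV to every row of a set.

    The returned set carries the preprocessing fingerprint used by
    :func:`ramancal.pls.predict` to reject incompatible model/data pairs.
    """
    step = _uniform_step(sset.grid)
    if sset.n_channels < config.sg_window:
        raise ValueError(
            f"{sset.n_channels} channels is fewer than the "
            f"{config.sg_window}-point SG window"
        )
    deriv = savgol_filter(
        sset.intensities,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.sg_deriv,
        delta=step,
        axis=1,
    )
    h = config.half_window
    grid = sset.grid[h:-h].copy()
    matrix = deriv[:, h:-h]
    if config.snv:
        mean = matrix.mean(axis=1, keepdims=True)
        sd = matrix.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() <= config.sd_floor)
        if bad.size:
            ids = [sset.sample_ids[i] for i in bad]
            raise ValueError(
                f"SNV: spectra with standard deviation at or below the floor "
                f"{config.sd_floor:g}: {ids}"
            )
        matrix = (matrix - mean) / sd
    return SpectraSet(
        grid,
        matrix,
        sset.references.copy(),
        fingerprint=config.fingerprint(grid),
    )
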