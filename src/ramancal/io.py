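"""Spectrum containers, CSV interchange, and wavenumber-grid standardization.

Raman spectrometers differ in spectral coverage and in the pixel-to-wavenumber
mapping, so spectra acquired on different instruments cannot be stacked
column-wise as they come off the detector.  This module defines the two
in-memory containers used throughout the package (:class:`Spectrum` and
:class:`SpectraSet`), the wide-CSV interchange format, and the cubic-spline
re-sampling that recalculates every spectrum onto one common wavenumber grid —
after which heterogeneous instruments become column-compatible and a single
intensity matrix can be assembled.

The default common grid runs from 300 cm^-1 upward in steps of 3 cm^-1,
staying at or below 3400 cm^-1 (1034 channels, last node 3399 cm^-1).  It is
the largest 3 cm^-1 ladder inside the spectral range shared by the supported
instrument families, so standardization never has to extrapolate.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: Analytes modeled throughout the package, in canonical order.
ANALYTES = ("glucose", "lactate", "glutamine", "glutamate")

#: Reference-table columns holding concentrations, one per analyte (g/L).
CONCENTRATION_COLUMNS = tuple(f"{a}_g_L" for a in ANALYTES)

#: Full reference-table schema.
REFERENCE_COLUMNS = ("sample_id", "batch_id", "site_id", "time_h") + CONCENTRATION_COLUMNS

WAVENUMBER_COLUMN = "wavenumber_cm1"

#: Common-grid definition: 300 cm^-1 up to (at most) 3400 cm^-1 in 3 cm^-1 steps.
GRID_START = 300.0
GRID_STOP = 3400.0
GRID_STEP = 3.0

# %.17g round-trips any float64 exactly through text.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum on its native wavenumber grid.

    Attributes
    ----------
    wavenumbers
        Strictly increasing Raman shifts in cm^-1.
    intensities
        Scattering intensities in arbitrary units, same length as the grid.
    sample_id, batch_id, site_id, instrument_id, time_h
        Provenance metadata carried through standardization and preprocessing.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    batch_id: str = ""
    site_id: str = ""
    instrument_id: str = ""
    time_h: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)
        if w.ndim != 1 or x.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D arrays")
        if w.size != x.size:
            raise ValueError(
                f"length mismatch: {w.size} wavenumbers vs {x.size} intensities"
            )
        if w.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in spectrum '{self.sample_id}'")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError(
                f"wavenumbers must be strictly increasing (spectrum '{self.sample_id}')"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class SpectraSet:
    """Grid-aligned spectra joined to their reference concentration table.

    The intensity matrix is samples x channels; ``references`` is a
    row-aligned :class:`pandas.DataFrame` following :data:`REFERENCE_COLUMNS`
    (concentrations in g/L; missing off-line values may be NaN).
    ``fingerprint`` identifies the preprocessing state (``None`` = raw).
    """

    grid: np.ndarray
    intensities: np.ndarray
    references: pd.DataFrame
    fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensity matrix must be 2-D (samples x channels)")
        if self.intensities.shape[1] != self.grid.size:
            raise ValueError(
                f"matrix has {self.intensities.shape[1]} columns but grid has "
                f"{self.grid.size} points"
            )
        if "sample_id" not in self.references.columns:
            raise ValueError("reference table lacks a 'sample_id' column")
        if len(self.references) != self.intensities.shape[0]:
            raise ValueError(
                f"{self.intensities.shape[0]} spectra but "
                f"{len(self.references)} reference rows"
            )
        ids = self.references["sample_id"].tolist()
        dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
        if dupes:
            raise ValueError(f"duplicated sample ids: {dupes}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.references["sample_id"].tolist()

    def concentrations(self, analyte: str) -> np.ndarray:
        """Reference concentrations (g/L) for one analyte, NaN if missing."""
        col = f"{analyte}_g_L"
        if col not in self.references.columns:
            raise KeyError(f"no reference column for analyte '{analyte}'")
        return self.references[col].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SpectraSet":
        """Row subset by boolean mask; preserves the preprocessing fingerprint."""
        mask = np.asarray(mask, dtype=bool)
        return SpectraSet(
            self.grid.copy(),
            self.intensities[mask].copy(),
            self.references.loc[mask].reset_index(drop=True),
            fingerprint=self.fingerprint,
        )


# -- wide-CSV interchange ------------------------------------------------------


def read_spectra(path) -> list[Spectrum]:
    """Read a wide spectra CSV: ``wavenumber_cm1`` column, one column per sample.

    Raises a descriptive :class:`ValueError` for a malformed header,
    duplicated sample-id columns, a non-increasing wavenumber column, or
    empty/ragged intensity columns.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split(",")
    if not header or header[0] != WAVENUMBER_COLUMN:
        raise ValueError(
            f"first column of '{path}' must be '{WAVENUMBER_COLUMN}', got "
            f"'{header[0] if header else ''}'"
        )
    ids = header[1:]
    if not ids:
        raise ValueError(f"'{path}' contains no intensity columns")
    dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
    if dupes:
        raise ValueError(f"duplicated sample id column(s) in '{path}': {dupes}")

    df = pd.read_csv(path, float_precision="round_trip")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    if w.size == 0:
        raise ValueError(f"'{path}' contains no spectral rows")
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise ValueError(f"non-increasing wavenumber column in '{path}'")

    spectra = []
    for j, sid in enumerate(ids, start=1):
        col = df.iloc[:, j]
        if col.isna().all():
            raise ValueError(f"empty intensity column for sample '{sid}' in '{path}'")
        if col.isna().any():
            raise ValueError(f"missing intensity values for sample '{sid}' in '{path}'")
        spectra.append(Spectrum(w, col.to_numpy(dtype=float), sample_id=str(sid)))
    return spectra


def write_spectra(spectra: "SpectraSet | Iterable[Spectrum]", path) -> None:
    """Write spectra as a wide CSV (lossless at full float64 precision).

    Accepts a :class:`SpectraSet` or an iterable of :class:`Spectrum` that all
    share one wavenumber grid.
    """
    if isinstance(spectra, SpectraSet):
        grid = spectra.grid
        data = {WAVENUMBER_COLUMN: grid}
        for i, sid in enumerate(spectra.sample_ids):
            data[str(sid)] = spectra.intensities[i]
    else:
        spectra = list(spectra)
        if not spectra:
            raise ValueError("no spectra to write")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise ValueError(
                    "spectra are on different grids; standardize before writing"
                )
        data = {WAVENUMBER_COLUMN: grid}
        for s in spectra:
            data[s.sample_id] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_references(path) -> pd.DataFrame:
    """Read a reference concentration table, validating the schema."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "batch_id": str, "site_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference table '{path}' lacks columns: {missing}")
    for col in ("time_h",) + CONCENTRATION_COLUMNS:
        df[col] = df[col].astype(float)
    ids = df["sample_id"].tolist()
    dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
    if dupes:
        raise ValueError(f"duplicated sample ids in reference table: {dupes}")
    return df


def write_references(references: pd.DataFrame, path) -> None:
    references.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- grid standardization ------------------------------------------------------


def default_target_grid(
    start: float = GRID_START, stop: float = GRID_STOP, step: float = GRID_STEP
) -> np.ndarray:
    """The common wavenumber grid: the largest ``step`` ladder from ``start``
    not exceeding ``stop`` (defaults: 300, 303, ..., 3399 cm^-1; 1034 points)."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(np.floor((stop - start) / step)) + 1
    if n < 1:
        raise ValueError("empty target grid")
    return start + step * np.arange(n, dtype=float)


def standardize_grid(spectrum: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Re-sample one spectrum onto ``target_grid`` by cubic-spline interpolation.

    A not-a-knot cubic spline is fit through the native samples and evaluated
    at the target nodes, so spectra from different spectrometers are
    recalculated as if acquired on a single instrument.  Extrapolation is
    never performed: any target node outside the native span is an error.
    """
    t = np.asarray(target_grid, dtype=float)
    w = spectrum.wavenumbers
    if t.size == 0:
        raise ValueError("empty target grid")
    if t[0] < w[0] or t[-1] > w[-1]:
        raise ValueError(
            f"target grid [{t[0]:g}, {t[-1]:g}] cm^-1 extends outside the source "
            f"span [{w[0]:g}, {w[-1]:g}] cm^-1 of spectrum '{spectrum.sample_id}'; "
            "extrapolation is not allowed"
        )
    if np.array_equal(w, t):
        values = spectrum.intensities.copy()
    else:
        spline = CubicSpline(w, spectrum.intensities, bc_type="not-a-knot")
        values = spline(t)
    return Spectrum(
        t.copy(),
        values,
        sample_id=spectrum.sample_id,
        batch_id=spectrum.batch_id,
        site_id=spectrum.site_id,
        instrument_id=spectrum.instrument_id,
        time_h=spectrum.time_h,
    )


def standardize_set(sset: SpectraSet, target_grid: np.ndarray) -> SpectraSet:
    """Vectorized :func:`standardize_grid` for a whole :class:`SpectraSet`."""
    t = np.asarray(target_grid, dtype=float)
    w = sset.grid
    if t[0] < w[0] or t[-1] > w[-1]:
        raise ValueError(
            f"target grid [{t[0]:g}, {t[-1]:g}] cm^-1 extends outside the source "
            f"span [{w[0]:g}, {w[-1]:g}] cm^-1; extrapolation is not allowed"
        )
    if np.array_equal(w, t):
        matrix = sset.intensities.copy()
    else:
        spline = CubicSpline(w, sset.intensities, axis=1, bc_type="not-a-knot")
        matrix = spline(t)
    return SpectraSet(t.copy(), matrix, sset.references.copy(), fingerprint=None)


def assemble_set(
    spectra: Sequence[Spectrum],
    references: pd.DataFrame,
    target_grid: np.ndarray | None = None,
) -> SpectraSet:
    """Standardize spectra onto one grid and join them to the reference table.

    Every spectrum's ``sample_id`` must appear in ``references``; reference
    rows without a spectrum are ignored with a logged warning.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to assemble")
    if target_grid is None:
        target_grid = default_target_grid()
    ids = [s.sample_id for s in spectra]
    dupes = sorted(i for i, c in Counter(ids).items() if c > 1)
    if dupes:
        raise ValueError(f"duplicated sample ids among spectra: {dupes}")
    ref_ids = set(references["sample_id"])
    missing = [i for i in ids if i not in ref_ids]
    if missing:
        raise ValueError(f"no reference rows for sample ids: {missing}")
    extra = ref_ids.difference(ids)
    if extra:
        logger.warning(
            "%d reference rows have no spectrum and are ignored: %s",
            len(extra),
            sorted(extra)[:5],
        )
    matrix = np.vstack(
        [standardize_grid(s, target_grid).intensities for s in spectra]
    )
    refs = (
        references.set_index("sample_id")
        .loc[ids]
        .reset_index()
        .reset_index(drop=True)
    )
    return SpectraSet(np.asarray(target_grid, dtype=float), matrix, refs)


def concat_sets(sets: Sequence[SpectraSet]) -> SpectraSet:
    """Stack several grid-compatible sets into one (e.g. pooling sites)."""
    if not sets:
        raise ValueError("no sets to concatenate")
    grid = sets[0].grid
    fp = sets[0].fingerprint
    for s in sets[1:]:
        if not np.array_equal(s.grid, grid):
            raise ValueError("cannot concatenate sets on different grids")
        if s.fingerprint != fp:
            raise ValueError("cannot concatenate sets with different fingerprints")
    matrix = np.vstack([s.intensities for s in sets])
    refs = pd.concat([s.references for s in sets], ignore_index=True)
    return SpectraSet(grid.copy(), matrix, refs, fingerprint=fp)
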