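"""Seeded synthetic Raman datasets: multi-site corpus, dilution series, cultures.

Real calibration corpora of in-line Raman spectra from industrial CHO
cultivations are proprietary, so this module generates surrogate data with the
statistical structure the downstream analysis assumes:

* a stylized band library per analyte (glucose, lactate, glutamine,
  glutamate) with partially overlapping Gaussian/Lorentzian bands, intensity
  linear in concentration — glutamate's coefficients are set ~20x weaker than
  glucose's so it remains the hard analyte;
* a constant "medium matrix" background (water bending/stretching and broad
  organic bands) that dominates total intensity, as it does in real
  cell-culture spectra;
* per-instrument characteristics (native grid, wavenumber miscalibration
  offset, peak broadening, additive noise, smooth polynomial baseline drift,
  multiplicative scatter) so that spectra from different instrument profiles
  are NOT column-compatible until grid standardization;
* fed-batch metabolite trajectories: glucose consumed between daily feed
  events and replenished only at feeds, lactate produced while glucose is
  consumed and later declining, glutamine/glutamate held in a low range.

All randomness flows from an explicit seed through
:class:`numpy.random.SeedSequence`, so identical (config, seed) pairs yield
bit-identical datasets.

A spectrum is built as::

    I(v) = m * [ sum_a c_a * sum_b coeff_b * shape((v - center_b - offset) / (width_b * broadening))
                 + matrix(v) ]
           + baseline(v) + eps(v)

with ``m`` a per-spectrum log-normal scatter factor, ``baseline`` a
random-coefficient polynomial, and ``eps`` i.i.d. Gaussian channel noise.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, fields, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .io import ANALYTES, SpectraSet, Spectrum

__all__ = [
    "Band",
    "AnalytePeakModel",
    "InstrumentProfile",
    "KineticsConfig",
    "CultureTrajectory",
    "SiteSpec",
    "MOLAR_MASS_G_PER_MOL",
    "mmol_per_l_to_g_per_l",
    "as_rng",
    "simulate_culture_trajectory",
    "generate_spectrum",
    "generate_dilution_series",
    "generate_multisite_dataset",
    "generate_culture_dataset",
    "load_peak_library",
    "load_instruments",
    "load_site_specs",
    "load_dilution_config",
    "load_culture_config",
    "DEFAULT_DILUTION_LEVELS",
]

#: Dilution-series concentration levels (g/L), measured in triplicate.
DEFAULT_DILUTION_LEVELS = (100.0, 50.0, 40.0, 30.0, 20.0, 11.0, 9.0, 7.0, 5.0, 3.0)

#: Molar masses used to convert literature mmol/L figures to g/L.
MOLAR_MASS_G_PER_MOL = {
    "glucose": 180.16,
    "lactate": 90.08,
    "glutamine": 146.15,
    "glutamate": 147.13,
}

_SHAPES = ("gaussian", "lorentzian")

# Band centers must stay inside the common standardized range.
_CENTER_LO, _CENTER_HI = 300.0, 3400.0


def mmol_per_l_to_g_per_l(value_mmol_l: float, analyte: str) -> float:
    """Convert a concentration in mmol/L to g/L using fixed molar masses."""
    return value_mmol_l * MOLAR_MASS_G_PER_MOL[analyte] / 1000.0


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- band library --------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One spectral band: center and width in cm^-1, amplitude coefficient in
    arbitrary units per g/L (or absolute a.u. for matrix bands)."""

    center: float
    width: float
    shape: str = "gaussian"
    coeff: float = 1.0

    def __post_init__(self) -> None:
        if not (_CENTER_LO <= self.center <= _CENTER_HI):
            raise ValueError(
                f"band center {self.center} cm^-1 outside "
                f"[{_CENTER_LO:g}, {_CENTER_HI:g}] cm^-1"
            )
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.coeff < 0:
            raise ValueError("band intensity coefficient must be non-negative")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown band shape '{self.shape}'")

    def profile(
        self, grid: np.ndarray, offset: float = 0.0, broadening: float = 1.0
    ) -> np.ndarray:
        """Unit-concentration band profile on ``grid`` (already scaled by coeff)."""
        z = (grid - self.center - offset) / (self.width * broadening)
        if self.shape == "gaussian":
            return self.coeff * np.exp(-0.5 * z * z)
        return self.coeff / (1.0 + z * z)


@dataclass(frozen=True)
class AnalytePeakModel:
    """Stylized band set of one analyte (at least one band)."""

    analyte: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if not self.bands:
            raise ValueError(f"analyte '{self.analyte}' needs at least one band")

    def signal(
        self, grid: np.ndarray, concentration: float, offset: float, broadening: float
    ) -> np.ndarray:
        out = np.zeros_like(grid)
        for b in self.bands:
            out += b.profile(grid, offset, broadening)
        return concentration * out


# -- instruments ---------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentProfile:
    """Synthetic spectrometer characteristics.

    The native grid must cover the common 300-3400 cm^-1 range so that grid
    standardization never extrapolates.  ``offset_cm1`` models wavenumber
    miscalibration; ``broadening`` multiplies every band width; the baseline
    is a random polynomial of the given degree scaled by ``baseline_scale``.

    ``offset_jitter_sd`` / ``broadening_jitter_sd`` model session-to-session
    response drift (probe alignment, fouling, temperature): each batch sees
    the instrument's systematic offset/broadening perturbed by these amounts.
    Without such drift an instrument's signature is perfectly deterministic,
    and a pooled calibration can exploit it in ways that do not transfer.
    """

    name: str
    grid_start: float
    grid_stop: float
    grid_step: float
    offset_cm1: float = 0.0
    broadening: float = 1.0
    noise_sd: float = 0.0
    baseline_degree: int = 3
    baseline_scale: float = 0.0
    scatter_sd: float = 0.0
    offset_jitter_sd: float = 0.0
    broadening_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.offset_jitter_sd < 0 or self.broadening_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.grid_step <= 0:
            raise ValueError("grid increment must be positive")
        if self.noise_sd < 0 or self.scatter_sd < 0 or self.baseline_scale < 0:
            raise ValueError("noise/scatter/baseline scales must be non-negative")
        if self.baseline_degree < 0:
            raise ValueError("baseline degree must be non-negative")
        if self.broadening <= 0:
            raise ValueError("broadening factor must be positive")
        g = self.grid()
        if g[0] > _CENTER_LO or g[-1] < _CENTER_HI:
            raise ValueError(
                f"instrument '{self.name}' grid [{g[0]:g}, {g[-1]:g}] does not "
                f"cover the common range [{_CENTER_LO:g}, {_CENTER_HI:g}] cm^-1"
            )

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n, dtype=float)


# -- fed-batch kinetics --------------------------------------------------------


@dataclass(frozen=True)
class KineticsConfig:
    """Fed-batch kinetics (all concentrations g/L, rates per hour).

    Glucose is consumed at a rate that ramps in with cell growth and is
    replenished to ``glucose_setpoint`` at daily feed events; lactate is
    produced in proportion to glucose consumption until the metabolic shift at
    ``lactate_switch_h`` and consumed (first-order) afterwards; glutamine is
    consumed and fed back to its setpoint; glutamate accumulates slowly from
    glutamine metabolism.

    ``batch_variability`` is the relative log-normal jitter applied per batch
    to initial values and rates; ``lactate_variability`` is the (larger)
    jitter on the lactate yield, initial level and metabolic-shift time,
    reflecting how strongly lactate metabolism differs between cell lines and
    process conditions.  That diversity is what lets a pooled calibration
    decorrelate lactate from glucose instead of using one as a proxy for the
    other.
    """

    duration_h: float = 240.0
    glucose_initial: float = 12.0
    glucose_setpoint: float = 12.0
    glucose_uptake_max: float = 0.35
    uptake_ramp_h: float = 48.0
    feed_start_h: float = 24.0
    feed_interval_h: float = 24.0
    lactate_initial: float = 0.3
    lactate_yield: float = 0.12
    lactate_switch_h: float = 150.0
    lactate_decay_per_h: float = 0.02
    glutamine_initial: float = 0.45
    glutamine_setpoint: float = 0.40
    glutamine_uptake_per_h: float = 0.02
    glutamate_initial: float = 0.06
    glutamate_yield: float = 0.10
    glutamate_uptake_per_h: float = 0.01
    batch_variability: float = 0.2
    lactate_variability: float = 0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"kinetics parameter '{f.name}' is not finite")
            if v < 0:
                raise ValueError(f"kinetics parameter '{f.name}' must be >= 0")
        if self.feed_interval_h <= 0 or self.uptake_ramp_h <= 0:
            raise ValueError("feed interval and uptake ramp must be positive")


@dataclass(frozen=True)
class CultureTrajectory:
    """Sampled metabolite trajectory of one fed-batch culture."""

    time_h: np.ndarray
    concentrations: dict[str, np.ndarray]
    feed_times_h: np.ndarray
    batch_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(
            self,
            "concentrations",
            {k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()},
        )
        object.__setattr__(
            self, "feed_times_h", np.asarray(self.feed_times_h, dtype=float)
        )
        if t.size == 0:
            raise ValueError("empty trajectory")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        for name, series in self.concentrations.items():
            if series.size != t.size:
                raise ValueError(f"series '{name}' length mismatch")
            if np.any(series < 0) or not np.all(np.isfinite(series)):
                raise ValueError(f"series '{name}' must be finite and non-negative")

    def __len__(self) -> int:
        return self.time_h.size

    def at(self, index: int) -> dict[str, float]:
        """Concentrations of all analytes at one sampling index."""
        return {k: float(v[index]) for k, v in self.concentrations.items()}


def _jitter(rng: np.random.Generator, value: float, rel_sd: float) -> float:
    return value * float(np.exp(rng.normal(0.0, rel_sd)))


def simulate_culture_trajectory(
    duration_h: float,
    interval_h: float,
    kinetics: KineticsConfig = KineticsConfig(),
    seed=0,
    batch_id: str = "",
    site_id: str = "",
) -> CultureTrajectory:
    """Simulate one fed-batch culture sampled every ``interval_h`` hours.

    Glucose strictly decreases between feed events (consumption only) and can
    increase only through a feed bolus; a feed at time ``f`` affects samples
    taken strictly after ``f`` (a sample coinciding with a feed is drawn just
    before the bolus).  Randomness enters only through per-batch log-normal
    jitter of initial values and rates, so two runs with the same seed and
    config are identical.
    """
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    if interval_h <= 0:
        raise ValueError("sampling interval must be positive")
    rng = as_rng(seed)
    k = kinetics
    v = k.batch_variability
    vl = k.lactate_variability
    # Fixed draw order keeps the seeding contract independent of branching.
    glucose = _jitter(rng, k.glucose_initial, v)
    setpoint = _jitter(rng, k.glucose_setpoint, v)
    uptake_max = _jitter(rng, k.glucose_uptake_max, v)
    lactate = _jitter(rng, k.lactate_initial, vl)
    lactate_yield = _jitter(rng, k.lactate_yield, vl)
    lactate_switch = _jitter(rng, k.lactate_switch_h, vl / 2)
    glutamine = _jitter(rng, k.glutamine_initial, v)
    glutamate = _jitter(rng, k.glutamate_initial, v)
    glutamate_yield = _jitter(rng, k.glutamate_yield, v)

    n_samples = int(math.floor(duration_h / interval_h + 1e-9)) + 1
    sample_times = interval_h * np.arange(n_samples, dtype=float)
    if k.feed_start_h <= duration_h:
        n_feeds = int(math.floor((duration_h - k.feed_start_h) / k.feed_interval_h + 1e-9)) + 1
        feed_times = k.feed_start_h + k.feed_interval_h * np.arange(n_feeds)
    else:
        feed_times = np.array([], dtype=float)

    events = sorted(
        set(np.round(sample_times, 9)).union(np.round(feed_times, 9))
    )
    feed_set = set(np.round(feed_times, 9))
    sample_set = set(np.round(sample_times, 9))

    records: dict[str, list[float]] = {a: [] for a in ANALYTES}

    def record() -> None:
        records["glucose"].append(glucose)
        records["lactate"].append(lactate)
        records["glutamine"].append(glutamine)
        records["glutamate"].append(glutamate)

    t = 0.0
    if 0.0 in sample_set:
        record()
    max_dt = 0.25
    for te in events:
        if te <= 0.0:
            continue
        # integrate (t, te] with sub-steps
        span = te - t
        n_sub = max(1, int(math.ceil(span / max_dt)))
        dt = span / n_sub
        for i in range(n_sub):
            tm = t + (i + 0.5) * dt  # midpoint time for the rate ramp
            ramp = 1.0 - math.exp(-tm / k.uptake_ramp_h)
            dg = min(uptake_max * ramp * dt, glucose)
            glucose -= dg
            if tm < lactate_switch:
                lactate += lactate_yield * dg
            else:
                lactate -= k.lactate_decay_per_h * lactate * dt
            dq = min(k.glutamine_uptake_per_h * ramp * glutamine * dt, glutamine)
            glutamine -= dq
            glutamate += glutamate_yield * dq - k.glutamate_uptake_per_h * glutamate * dt
            glucose = max(glucose, 0.0)
            lactate = max(lactate, 0.0)
            glutamine = max(glutamine, 0.0)
            glutamate = max(glutamate, 0.0)
        t = te
        key = round(te, 9)
        if key in sample_set:
            record()  # sample before any feed at the same instant
        if key in feed_set:
            glucose += max(0.0, setpoint - glucose)
            glutamine += max(0.0, k.glutamine_setpoint - glutamine)

    return CultureTrajectory(
        sample_times,
        {a: np.array(records[a]) for a in ANALYTES},
        feed_times,
        batch_id=batch_id,
        site_id=site_id,
    )


# -- spectrum synthesis --------------------------------------------------------


def _peak_map(
    peaks: "Sequence[AnalytePeakModel] | Mapping[str, AnalytePeakModel]",
) -> dict[str, AnalytePeakModel]:
    if isinstance(peaks, Mapping):
        return dict(peaks)
    return {p.analyte: p for p in peaks}


def generate_spectrum(
    concentrations: Mapping[str, float],
    profile: InstrumentProfile,
    peaks: "Sequence[AnalytePeakModel] | Mapping[str, AnalytePeakModel]",
    seed=0,
    matrix_bands: Sequence[Band] = (),
    sample_id: str = "",
    batch_id: str = "",
    site_id: str = "",
    time_h: float = 0.0,
) -> Spectrum:
    """Synthesize one spectrum on the instrument's native grid.

    The analyte signal is strictly linear in concentration; the constant
    matrix background, the random polynomial baseline, the per-spectrum
    scatter factor and the channel noise are the nuisance terms the
    preprocessing chain is designed to remove.
    """
    rng = as_rng(seed)
    lib = _peak_map(peaks)
    grid = profile.grid()
    signal = np.zeros_like(grid)
    for analyte, conc in concentrations.items():
        if not np.isfinite(conc) or conc < 0:
            raise ValueError(
                f"concentration of '{analyte}' must be finite and >= 0, got {conc}"
            )
        if analyte not in lib:
            raise KeyError(f"analyte '{analyte}' missing from the peak library")
        signal += lib[analyte].signal(
            grid, conc, profile.offset_cm1, profile.broadening
        )
    for band in matrix_bands:
        signal += band.profile(grid, profile.offset_cm1, profile.broadening)

    # Fixed draw order: baseline coefficients, scatter, channel noise.
    coeffs = rng.normal(0.0, 1.0, profile.baseline_degree + 1)
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = profile.baseline_scale * np.polynomial.polynomial.polyval(u, coeffs)
    scatter = float(np.exp(rng.normal(0.0, profile.scatter_sd)))
    noise = rng.normal(0.0, profile.noise_sd, grid.size)
    return Spectrum(
        grid,
        scatter * signal + baseline + noise,
        sample_id=sample_id,
        batch_id=batch_id,
        site_id=site_id,
        instrument_id=profile.name,
        time_h=time_h,
    )


def _reference_row(
    sample_id: str, batch_id: str, site_id: str, time_h: float, conc: Mapping[str, float]
) -> dict:
    row = {
        "sample_id": sample_id,
        "batch_id": batch_id,
        "site_id": site_id,
        "time_h": time_h,
    }
    for a in ANALYTES:
        row[f"{a}_g_L"] = float(conc.get(a, np.nan))
    return row


def generate_dilution_series(
    profile: InstrumentProfile,
    peaks,
    matrix_bands: Sequence[Band] = (),
    levels: Sequence[float] = DEFAULT_DILUTION_LEVELS,
    replicates: int = 3,
    seed=0,
    site_id: str = "external",
    batch_id: str = "dilution",
    composition: Mapping[str, float] | None = None,
) -> SpectraSet:
    """Dilution series of the four analytes in a model medium.

    A stock solution is diluted to the given ``levels`` (the glucose
    concentration in g/L) and each dilution is measured ``replicates`` times;
    defaults are the ten levels 100...3 g/L in triplicate (30 samples,
    glucose reference range 97 g/L).  ``composition`` gives each analyte's
    concentration in the undiluted stock (at the maximum level); all analytes
    scale proportionally on dilution.  Without a composition every analyte is
    taken at the level concentration itself.  Reference values are exact
    (gravimetric preparation), unlike the assay-measured culture references.
    """
    levels = [float(x) for x in levels]
    if not levels:
        raise ValueError("dilution series needs at least one level")
    if any(x <= 0 for x in levels):
        raise ValueError("dilution levels must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    top = max(levels)
    rng = as_rng(seed)
    spectra, rows = [], []
    for i, level in enumerate(levels):
        if composition is None:
            conc = {a: level for a in ANALYTES}
        else:
            conc = {a: composition[a] * level / top for a in ANALYTES}
        for r in range(1, replicates + 1):
            sid = f"dil-{i:02d}-{level:g}gL-r{r}"
            s = generate_spectrum(
                conc,
                profile,
                peaks,
                rng,
                matrix_bands=matrix_bands,
                sample_id=sid,
                batch_id=batch_id,
                site_id=site_id,
            )
            spectra.append(s)
            rows.append(_reference_row(sid, batch_id, site_id, 0.0, conc))
    matrix = np.vstack([s.intensities for s in spectra])
    return SpectraSet(spectra[0].wavenumbers, matrix, pd.DataFrame(rows))


@dataclass(frozen=True)
class SiteSpec:
    """One site of the calibration corpus: an instrument, a number of batches,
    and the total spectrum count (distributed as evenly as possible over the
    batches)."""

    site_id: str
    profile: InstrumentProfile
    n_batches: int
    n_spectra: int
    kinetics: KineticsConfig = KineticsConfig()

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("each site needs at least one batch")
        if self.n_spectra < self.n_batches:
            raise ValueError("need at least one spectrum per batch")

    def batch_counts(self) -> list[int]:
        base, extra = divmod(self.n_spectra, self.n_batches)
        return [base + (1 if i < extra else 0) for i in range(self.n_batches)]


#: Relative SD of the off-line reference assay error (Cedex-analyzer-like).
DEFAULT_ASSAY_NOISE_REL = 0.02


def _batch_dataset(
    site_id: str,
    batch_id: str,
    profile: InstrumentProfile,
    kinetics: KineticsConfig,
    n_spectra: int,
    peaks,
    matrix_bands: Sequence[Band],
    seed,
    assay_noise_rel: float = DEFAULT_ASSAY_NOISE_REL,
) -> tuple[list[Spectrum], list[dict]]:
    """One seeded batch: a trajectory plus one spectrum per sampling time.

    Spectra are generated from the true trajectory concentrations; the
    reference rows carry the *measured* off-line values, i.e. truth plus a
    relative assay error, as a real analyzer would report.  The instrument's
    offset/broadening get one session-drift perturbation per batch.
    """
    rng = as_rng(seed)
    profile = replace(
        profile,
        offset_cm1=profile.offset_cm1
        + profile.offset_jitter_sd * float(rng.normal()),
        broadening=profile.broadening
        * float(np.exp(profile.broadening_jitter_sd * rng.normal())),
        offset_jitter_sd=0.0,
        broadening_jitter_sd=0.0,
    )
    if n_spectra == 1:
        duration, interval = 0.0, 1.0
    else:
        duration = kinetics.duration_h
        interval = duration / (n_spectra - 1)
    traj = simulate_culture_trajectory(
        duration, interval, kinetics, rng, batch_id=batch_id, site_id=site_id
    )
    assert len(traj) == n_spectra
    spectra, rows = [], []
    for i in range(n_spectra):
        conc = traj.at(i)
        t = float(traj.time_h[i])
        sid = f"{batch_id}-s{i:03d}"
        spectra.append(
            generate_spectrum(
                conc,
                profile,
                peaks,
                rng,
                matrix_bands=matrix_bands,
                sample_id=sid,
                batch_id=batch_id,
                site_id=site_id,
                time_h=t,
            )
        )
        measured = {
            a: max(0.0, c * (1.0 + assay_noise_rel * float(rng.normal())))
            for a, c in conc.items()
        }
        rows.append(_reference_row(sid, batch_id, site_id, t, measured))
    return spectra, rows


def generate_multisite_dataset(
    site_specs: Sequence[SiteSpec],
    peaks,
    matrix_bands: Sequence[Band] = (),
    seed=0,
    assay_noise_rel: float = DEFAULT_ASSAY_NOISE_REL,
) -> dict[str, SpectraSet]:
    """Generate the multi-site calibration corpus, one SpectraSet per site.

    Each batch is an independent seeded fed-batch trajectory; every spectrum
    is paired with the trajectory concentrations at its sampling time.  The
    per-site spectrum totals follow the site specs exactly.
    """
    if not site_specs:
        raise ValueError("no site specs given")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    site_children = ss.spawn(len(site_specs))
    out: dict[str, SpectraSet] = {}
    for spec, child in zip(site_specs, site_children):
        batch_children = child.spawn(spec.n_batches)
        spectra: list[Spectrum] = []
        rows: list[dict] = []
        for b, (bseed, count) in enumerate(
            zip(batch_children, spec.batch_counts()), start=1
        ):
            batch_id = f"{spec.site_id}-b{b:02d}"
            s, r = _batch_dataset(
                spec.site_id,
                batch_id,
                spec.profile,
                spec.kinetics,
                count,
                peaks,
                matrix_bands,
                np.random.default_rng(bseed),
                assay_noise_rel=assay_noise_rel,
            )
            spectra.extend(s)
            rows.extend(r)
        matrix = np.vstack([s.intensities for s in spectra])
        out[spec.site_id] = SpectraSet(
            spectra[0].wavenumbers, matrix, pd.DataFrame(rows)
        )
    return out


def generate_culture_dataset(
    profile: InstrumentProfile,
    kinetics: KineticsConfig,
    n_spectra: int,
    seed=0,
    site_id: str = "external",
    batch_id: str = "culture",
    peaks=None,
    matrix_bands: Sequence[Band] = (),
    assay_noise_rel: float = DEFAULT_ASSAY_NOISE_REL,
) -> SpectraSet:
    """An independent fed-batch culture on its own instrument (one batch)."""
    if peaks is None:
        peaks, default_matrix = load_peak_library()
        if not matrix_bands:
            matrix_bands = default_matrix
    spectra, rows = _batch_dataset(
        site_id, batch_id, profile, kinetics, n_spectra, peaks, matrix_bands, seed,
        assay_noise_rel=assay_noise_rel,
    )
    matrix = np.vstack([s.intensities for s in spectra])
    return SpectraSet(spectra[0].wavenumbers, matrix, pd.DataFrame(rows))


# -- packaged configuration ----------------------------------------------------


def _load_yaml(name: str) -> dict:
    text = resources.files("ramancal").joinpath("configs", name).read_text()
    return yaml.safe_load(text)


def _band_list(entries: Sequence[dict]) -> tuple[Band, ...]:
    return tuple(
        Band(
            center=float(e["center"]),
            width=float(e["width"]),
            shape=str(e.get("shape", "gaussian")),
            coeff=float(e["coeff"]),
        )
        for e in entries
    )


def load_peak_library() -> tuple[list[AnalytePeakModel], tuple[Band, ...]]:
    """Packaged default band library: (analyte peak models, matrix bands)."""
    cfg = _load_yaml("peaks.yaml")
    models = [
        AnalytePeakModel(analyte=a, bands=_band_list(cfg["analytes"][a]))
        for a in cfg["analytes"]
    ]
    matrix = _band_list(cfg.get("matrix", []))
    return models, matrix


def load_instruments() -> dict[str, InstrumentProfile]:
    cfg = _load_yaml("instruments.yaml")
    return {
        name: InstrumentProfile(name=name, **params) for name, params in cfg.items()
    }


def load_site_specs(scenario: str = "desk") -> list[SiteSpec]:
    """Packaged site specifications: ``full`` (305/958/295/148 spectra over
    6/22/4/7 batches) or ``desk`` (~10% per site for fast runs)."""
    if scenario not in ("desk", "full"):
        raise ValueError(f"unknown scenario '{scenario}'")
    cfg = _load_yaml(f"sites_{scenario}.yaml")
    instruments = load_instruments()
    specs = []
    for entry in cfg["sites"]:
        kin = replace(KineticsConfig(), **entry.get("kinetics", {}))
        specs.append(
            SiteSpec(
                site_id=entry["site_id"],
                profile=instruments[entry["instrument"]],
                n_batches=int(entry["n_batches"]),
                n_spectra=int(entry["n_spectra"]),
                kinetics=kin,
            )
        )
    return specs


def load_dilution_config() -> dict:
    """Packaged dilution-series config: levels, replicates, instrument."""
    cfg = _load_yaml("dilution.yaml")
    instruments = load_instruments()
    comp = cfg.get("composition")
    return {
        "levels": [float(x) for x in cfg["levels"]],
        "replicates": int(cfg["replicates"]),
        "profile": instruments[cfg["instrument"]],
        "composition": None if comp is None else {k: float(v) for k, v in comp.items()},
    }


def load_culture_config() -> dict:
    """Packaged independent-culture config (held-out instrument and kinetics)."""
    cfg = _load_yaml("culture.yaml")
    instruments = load_instruments()
    return {
        "profile": instruments[cfg["instrument"]],
        "kinetics": replace(KineticsConfig(), **cfg.get("kinetics", {})),
        "n_spectra": int(cfg["n_spectra"]),
        "site_id": cfg.get("site_id", "external"),
        "batch_id": cfg.get("batch_id", "culture"),
    }
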