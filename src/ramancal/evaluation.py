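"""Figures of merit (RMSE, R², SEC%/SEP%) and the generic-transfer experiment.

The calibration and prediction errors are reported as

    RMSE = sqrt( (1/N) * sum_i (yhat_i - y_i)^2 )            [g/L]
    SEC or SEP (%) = 100 * RMSE / Yrange

where Yrange is the reference concentration range (highest minus smallest
value) of the evaluated set itself.  SEC (calibration) and SEP (test /
external prediction) use the identical formula; the role tag is metadata.
In bioprocess monitoring SEP below 5% is commonly regarded as very good and
above 10% as not acceptable; those thresholds are recorded as annotations,
never enforced.

R² defaults to the coefficient of determination 1 - SSres/SStot ("variability
captured by the model"); the squared Pearson correlation is available for
cross-checking.

:func:`run_generic_experiment` executes the whole study on seeded synthetic
data: calibrate per-site and pooled ("generic") models on the multi-site
corpus, validate each externally on a dilution series from a fifth, held-out
instrument, and apply the pooled models to an independent fed-batch culture
on yet another instrument.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .io import (
    ANALYTES,
    SpectraSet,
    concat_sets,
    default_target_grid,
    standardize_set,
)
from .pls import CVConfig, PLSModel, cross_validate, fit_pls, predict, \
    select_latent_variables, split_train_test
from .preprocess import PreprocessConfig, preprocess_set
from . import synth

#: SEP% interpretation thresholds (annotation only).
SEP_VERY_GOOD = 5.0
SEP_ACCEPTABLE = 10.0


def rmse(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square error between predictions and reference values."""
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.size == 0 or p.size != r.size:
        raise ValueError("predicted and reference must be non-empty, equal-length")
    d = p - r
    return float(np.sqrt(np.mean(d * d)))


def sep_percent(rmse_value: float, reference: np.ndarray) -> float:
    """SEC/SEP in percent: 100 * RMSE / (max - min of the reference values)."""
    r = np.asarray(reference, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty reference values")
    y_range = float(r.max() - r.min())
    if y_range <= 0:
        raise ValueError("reference range must be positive")
    return 100.0 * float(rmse_value) / y_range


def r_squared(
    predicted: np.ndarray, reference: np.ndarray, method: str = "determination"
) -> float:
    """R²: coefficient of determination (default) or squared Pearson r.

    The determination form can be negative for worse-than-mean predictions;
    that is the documented contract, not an error.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.size == 0 or p.size != r.size:
        raise ValueError("predicted and reference must be non-empty, equal-length")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("constant reference values")
    if method == "determination":
        ss_res = float(np.sum((p - r) ** 2))
        return 1.0 - ss_res / ss_tot
    if method == "pearson":
        return float(np.corrcoef(p, r)[0, 1]) ** 2
    raise ValueError(f"unknown R² method '{method}'")


def minmax_scale(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale values to [0, 1] for reporting; returns (scaled, (min, max)).

    Used only for presentation (proprietary-range masking); never inside
    model fitting.  SEP% is invariant under this scaling since numerator and
    denominator transform identically.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin <= 0:
        raise ValueError("range must be positive for min-max scaling")
    return (v - vmin) / (vmax - vmin), (vmin, vmax)


def inverse_minmax(scaled: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    vmin, vmax = params
    return np.asarray(scaled, dtype=float) * (vmax - vmin) + vmin


def classify_sep(sep: float) -> str:
    if sep < SEP_VERY_GOOD:
        return "very good"
    if sep <= SEP_ACCEPTABLE:
        return "acceptable"
    return "too high"


@dataclass(frozen=True)
class EvaluationReport:
    """One row of figures of merit for (analyte, model, role).

    SEP% = 100*RMSE/Yrange is re-verified at construction so every report row
    is internally consistent.
    """

    analyte: str
    model: str
    role: str  # calibration | test | external | independent
    n: int
    rmse_g_L: float
    r2: float
    sep_percent: float
    y_range_g_L: float
    n_lv: int
    annotation: str

    def __post_init__(self) -> None:
        if self.rmse_g_L < 0:
            raise ValueError("RMSE must be >= 0")
        if self.y_range_g_L <= 0:
            raise ValueError("Yrange must be positive")
        expected = 100.0 * self.rmse_g_L / self.y_range_g_L
        if abs(self.sep_percent - expected) > 1e-9 * max(1.0, expected):
            raise ValueError(
                f"inconsistent report row: SEP {self.sep_percent} != "
                f"100*RMSE/Yrange = {expected}"
            )


def evaluate_predictions(
    predicted: np.ndarray,
    reference: np.ndarray,
    *,
    analyte: str,
    model: str,
    role: str,
    n_lv: int,
) -> EvaluationReport:
    """Compute all figures of merit for one prediction task."""
    e = rmse(predicted, reference)
    sep = sep_percent(e, reference)
    r = np.asarray(reference, dtype=float).ravel()
    return EvaluationReport(
        analyte=analyte,
        model=model,
        role=role,
        n=int(r.size),
        rmse_g_L=e,
        r2=r_squared(predicted, reference),
        sep_percent=sep,
        y_range_g_L=float(r.max() - r.min()),
        n_lv=int(n_lv),
        annotation=classify_sep(sep),
    )


# -- the generic-transfer experiment ------------------------------------------


@dataclass
class ExperimentResult:
    """Outcome of :func:`run_generic_experiment`.

    ``reports`` has one row per (model, analyte, role); ``models`` maps model
    name -> analyte -> fitted :class:`~ramancal.pls.PLSModel`.
    """

    reports: pd.DataFrame
    models: dict[str, dict[str, PLSModel]]

    def row(self, model: str, analyte: str, role: str) -> pd.Series:
        df = self.reports
        sel = df[(df.model == model) & (df.analyte == analyte) & (df.role == role)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({model}, {analyte}, {role})")
        return sel.iloc[0]


def calibrate_analyte(
    train: SpectraSet,
    analyte: str,
    cv: CVConfig,
    *,
    stratify_key: str | None = "site_id",
    preprocess: dict | None = None,
    target_grid: dict | None = None,
) -> PLSModel:
    """Cross-validate, select the LV count, and fit one analyte model.

    Samples whose reference value is missing (NaN) are excluded.  CV folds
    are stratified by ``stratify_key`` (site by default) so that no fold
    strips an instrument out of the training data.
    """
    y = train.concentrations(analyte)
    ok = np.isfinite(y)
    X = train.intensities[ok]
    y = y[ok]
    groups = train.references.loc[ok, cv.group_key].to_numpy()
    stratify = (
        train.references.loc[ok, stratify_key].to_numpy()
        if stratify_key is not None and stratify_key in train.references.columns
        else None
    )
    curve = cross_validate(X, y, groups, cv, stratify=stratify)
    n_lv = select_latent_variables(curve, cv.selection_tol)
    return fit_pls(
        X,
        y,
        n_lv,
        analyte=analyte,
        fingerprint=train.fingerprint,
        grid=train.grid,
        rmsecv=curve,
        preprocess=preprocess,
        target_grid=target_grid,
    )


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_generic_experiment(
    seed: int = 0,
    scenario: str = "desk",
    preprocess_config: PreprocessConfig | None = None,
    cv_config: CVConfig | None = None,
    split_fraction: float = 0.7,
) -> ExperimentResult:
    """Run the multi-site calibration-transfer study on synthetic data.

    1. Generate the seeded multi-site corpus, standardize every site onto the
       common grid, preprocess, and pool the four sites into the "generic"
       calibration set.
    2. For the pooled set and each single site: split 70/30 by batch,
       cross-validate the LV count on the training batches, fit one PLS model
       per analyte, and report SEC (calibration) and SEP (test).
    3. Validate every model externally on a dilution series generated from a
       fifth, held-out instrument profile.
    4. Apply the pooled models to an independent fed-batch culture on yet
       another instrument.
    """
    pp = preprocess_config or PreprocessConfig()
    cv = cv_config or CVConfig()
    target = default_target_grid()

    ss = np.random.SeedSequence(seed)
    s_corpus, s_dil, s_cult, s_split, s_cv = ss.spawn(5)

    peaks, matrix_bands = synth.load_peak_library()
    sites = synth.load_site_specs(scenario)
    dil_cfg = synth.load_dilution_config()
    cult_cfg = synth.load_culture_config()

    raw_sites = synth.generate_multisite_dataset(
        sites, peaks, matrix_bands, seed=s_corpus
    )
    prep_sites = {
        sid: preprocess_set(standardize_set(s, target), pp)
        for sid, s in raw_sites.items()
    }
    pooled = concat_sets(list(prep_sites.values()))

    dil_raw = synth.generate_dilution_series(
        dil_cfg["profile"],
        peaks,
        matrix_bands,
        levels=dil_cfg["levels"],
        replicates=dil_cfg["replicates"],
        seed=s_dil,
        composition=dil_cfg.get("composition"),
    )
    dilution = preprocess_set(standardize_set(dil_raw, target), pp)

    cult_raw = synth.generate_culture_dataset(
        cult_cfg["profile"],
        cult_cfg["kinetics"],
        cult_cfg["n_spectra"],
        seed=s_cult,
        site_id=cult_cfg["site_id"],
        batch_id=cult_cfg["batch_id"],
        peaks=peaks,
        matrix_bands=matrix_bands,
    )
    culture = preprocess_set(standardize_set(cult_raw, target), pp)

    model_sets = {"pooled": pooled, **prep_sites}
    split_seed = _seed_int(s_split)
    cv_seed = _seed_int(s_cv)

    rows: list[EvaluationReport] = []
    models: dict[str, dict[str, PLSModel]] = {}
    for name, full_set in model_sets.items():
        train, test = split_train_test(
            full_set, split_fraction, seed=split_seed, stratify_key="site_id"
        )
        n_train_batches = train.references[cv.group_key].nunique()
        cv_local = replace(cv, folds=min(cv.folds, n_train_batches), seed=cv_seed)
        models[name] = {}
        for analyte in ANALYTES:
            model = calibrate_analyte(train, analyte, cv_local)
            models[name][analyte] = model
            rows.append(
                evaluate_predictions(
                    predict(model, train),
                    train.concentrations(analyte),
                    analyte=analyte, model=name, role="calibration",
                    n_lv=model.n_lv,
                )
            )
            rows.append(
                evaluate_predictions(
                    predict(model, test),
                    test.concentrations(analyte),
                    analyte=analyte, model=name, role="test", n_lv=model.n_lv,
                )
            )
            rows.append(
                evaluate_predictions(
                    predict(model, dilution),
                    dilution.concentrations(analyte),
                    analyte=analyte, model=name, role="external",
                    n_lv=model.n_lv,
                )
            )
            if name == "pooled":
                rows.append(
                    evaluate_predictions(
                        predict(model, culture),
                        culture.concentrations(analyte),
                        analyte=analyte, model=name, role="independent",
                        n_lv=model.n_lv,
                    )
                )
    reports = pd.DataFrame([asdict(r) for r in rows])
    return ExperimentResult(reports=reports, models=models)
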