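"""PLS1 regression (NIPALS) with batch-grouped cross-validated LV selection.

One model per analyte links the preprocessed spectral matrix X (samples x
channels) to the off-line concentration vector y (g/L) through the linear
model y = X B + e.  Components are extracted by the NIPALS algorithm with
X-only deflation:

    w_a = X_a' y / ||X_a' y||      (weights)
    t_a = X_a w_a                  (scores)
    p_a = X_a' t_a / (t_a' t_a)    (X loadings)
    q_a = y' t_a / (t_a' t_a)      (y loading)
    X_{a+1} = X_a - t_a p_a'

and the regression vector for A components is B = W (P'W)^{-1} q.  X is
mean-centered internally; channels are not variance-scaled (SNV has already
normalized the spectra).

The number of latent variables is chosen from an RMSECV curve computed by
group-wise cross-validation: all spectra of a cultivation batch stay in the
same fold, since spectra within a batch are serially correlated and a
per-spectrum split would understate the prediction error.  The chosen LV
count is the smallest one whose RMSECV lies within a tolerance (default 1%)
of the curve minimum — a parsimony rule that avoids chasing noise in flat
curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import SpectraSet

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for latent-variable selection."""

    folds: int = 10
    group_key: str = "batch_id"
    max_lv: int = 20
    selection_tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")
        if self.selection_tol < 0:
            raise ValueError("selection tolerance must be >= 0")


@dataclass
class PLSModel:
    """A fitted PLS1 calibration artifact for one analyte.

    Stores the centering vectors, the NIPALS weight/loading matrices (one
    column per extracted component), the regression coefficients for the
    chosen LV count, the RMSECV curve that justified the choice, and the
    preprocessing fingerprint + grid that incoming spectra must match.
    """

    analyte: str
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, channels x A
    x_loadings: np.ndarray    # P, channels x A
    y_loadings: np.ndarray    # q, A
    coef: np.ndarray          # B for n_lv components, channels
    n_lv: int
    rmsecv: np.ndarray | None = None
    fingerprint: str | None = None
    grid: np.ndarray | None = None
    preprocess: dict | None = None
    target_grid: dict | None = None
    version: str = "1.0"

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predictions for an already-preprocessed matrix: (X - x̄)B + ȳ."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.coef.size:
            raise ValueError(
                f"matrix has {X.shape[-1]} channels, model expects {self.coef.size}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "analyte": self.analyte,
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_lv": int(self.n_lv),
            "rmsecv": None if self.rmsecv is None else self.rmsecv.tolist(),
            "fingerprint": self.fingerprint,
            "grid": None if self.grid is None else self.grid.tolist(),
            "preprocess": self.preprocess,
            "target_grid": self.target_grid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            analyte=d["analyte"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_lv=int(d["n_lv"]),
            rmsecv=None if d.get("rmsecv") is None else np.asarray(d["rmsecv"]),
            fingerprint=d.get("fingerprint"),
            grid=None if d.get("grid") is None else np.asarray(d["grid"]),
            preprocess=d.get("preprocess"),
            target_grid=d.get("target_grid"),
            version=d.get("version", "1.0"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int, strict: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS1 on centered data; returns (W, P, q, T).

    With ``strict`` the requested component count must not exceed the
    predictive rank of X; otherwise extraction stops early and fewer columns
    are returned.
    """
    X = Xc.copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    c0 = float(np.linalg.norm(X.T @ yc))
    a_done = 0
    for a in range(n_lv):
        c = X.T @ yc
        cnorm = float(np.linalg.norm(c))
        if cnorm <= _RANK_TOL * max(c0, 1e-300):
            if strict:
                raise ValueError(
                    f"requested {n_lv} latent variables but X is exhausted "
                    f"after {a} components"
                )
            break
        w = c / cnorm
        t = X @ w
        tt = float(t @ t)
        if tt <= 0.0:
            if strict:
                raise ValueError("degenerate score vector in NIPALS")
            break
        pvec = (X.T @ t) / tt
        W[:, a] = w
        P[:, a] = pvec
        q[a] = float(yc @ t) / tt
        T[:, a] = t
        X -= np.outer(t, pvec)
        a_done = a + 1
    return W[:, :a_done], P[:, :a_done], q[:a_done], T[:, :a_done]


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector B = W_k (P_k' W_k)^{-1} q_k."""
    Wk = W[:, :k]
    M = P[:, :k].T @ Wk
    return Wk @ np.linalg.solve(M, q[:k])


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    *,
    analyte: str = "",
    fingerprint: str | None = None,
    grid: np.ndarray | None = None,
    rmsecv: np.ndarray | None = None,
    preprocess: dict | None = None,
    target_grid: dict | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` NIPALS components.

    X is mean-centered internally (no channel scaling).  Errors on non-finite
    input, zero-variance y, or an LV count exceeding the predictive rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per y value")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if X.shape[0] < n_lv + 1:
        raise ValueError(f"need at least n_lv + 1 = {n_lv + 1} samples")
    if float(np.std(y)) == 0.0:
        raise ValueError("zero-variance y")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals_pls1(X - x_mean, y - y_mean, n_lv, strict=True)
    coef = _coefficients(W, P, q, n_lv)
    return PLSModel(
        analyte=analyte,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        n_lv=n_lv,
        rmsecv=None if rmsecv is None else np.asarray(rmsecv, dtype=float),
        fingerprint=fingerprint,
        grid=None if grid is None else np.asarray(grid, dtype=float),
        preprocess=preprocess,
        target_grid=target_grid,
    )


def predict(model: PLSModel, sset: SpectraSet) -> np.ndarray:
    """Predict per-sample concentrations for a preprocessed set.

    The set's preprocessing fingerprint and grid must match the model's —
    silently applying a calibration to differently prepared spectra is the
    core transferability pitfall this check prevents.
    """
    if model.fingerprint is not None and sset.fingerprint != model.fingerprint:
        raise ValueError(
            f"preprocessing fingerprint mismatch: model '{model.fingerprint}' vs "
            f"data '{sset.fingerprint}'"
        )
    if model.grid is not None:
        if sset.n_channels != model.grid.size or not np.allclose(
            sset.grid, model.grid
        ):
            raise ValueError(
                f"grid mismatch: data has {sset.n_channels} channels, model was "
                f"trained on {model.grid.size}"
            )
    return model.predict_matrix(sset.intensities)


def _group_folds(
    groups: np.ndarray, folds: int, seed: int, strata: dict | None = None
) -> list[np.ndarray]:
    """Seeded partition of unique groups into ``folds`` near-equal parts.

    With ``strata`` (group -> stratum label, e.g. the site a batch came
    from), each stratum's groups are shuffled and dealt round-robin across
    folds so that no fold concentrates one stratum: every training fold then
    retains spectra from every instrument, mirroring the pooled-calibration
    design in which no instrument is ever absent from the calibration.
    """
    uniq = np.unique(groups)
    if uniq.size < folds:
        raise ValueError(
            f"grouped CV needs at least as many groups ({uniq.size}) as folds "
            f"({folds})"
        )
    rng = np.random.default_rng(seed)
    if strata is None:
        perm = uniq[rng.permutation(uniq.size)]
        return [np.asarray(part) for part in np.array_split(perm, folds)]
    fold_lists: list[list] = [[] for _ in range(folds)]
    pos = 0
    for s in sorted({strata[g] for g in uniq}):
        members = np.array([g for g in uniq if strata[g] == s])
        members = members[rng.permutation(members.size)]
        for g in members:
            fold_lists[pos % folds].append(g)
            pos += 1
    return [np.asarray(f) for f in fold_lists if f]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cv: CVConfig = CVConfig(),
    stratify: np.ndarray | None = None,
) -> np.ndarray:
    """RMSECV per LV count 1..max from group-wise cross-validation.

    Folds are formed over groups (all spectra of a batch stay together);
    out-of-fold predictions are pooled over all samples and scored with the
    root-mean-square error.  ``stratify`` (per-sample labels, e.g. site ids)
    spreads each stratum's groups across folds.  The usable LV ceiling is
    clamped to the smallest training-fold size minus one and to the channel
    count; in folds whose predictive rank is exhausted earlier, higher LV
    counts reuse the last valid component set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    strata = None
    if stratify is not None:
        stratify = np.asarray(stratify)
        strata = {g: stratify[groups == g][0] for g in np.unique(groups)}
    fold_groups = _group_folds(groups, cv.folds, cv.seed, strata)
    n, p = X.shape
    test_masks = []
    max_lv = min(cv.max_lv, p)
    n_groups = np.unique(groups).size
    for fg in fold_groups:
        mask = np.isin(groups, fg)
        if n_groups - fg.size < 2:
            raise ValueError(
                "a CV fold would leave fewer than 2 training groups"
            )
        test_masks.append(mask)
        max_lv = min(max_lv, int((~mask).sum()) - 1)
    if max_lv < 1:
        raise ValueError("not enough training samples for even one latent variable")

    preds = np.empty((max_lv, n))
    for mask in test_masks:
        Xtr, ytr = X[~mask], y[~mask]
        x_mean = Xtr.mean(axis=0)
        y_mean = float(ytr.mean())
        W, P, q, _ = _nipals_pls1(Xtr - x_mean, ytr - y_mean, max_lv, strict=False)
        a_avail = q.size
        Xte = X[mask] - x_mean
        for k in range(1, max_lv + 1):
            B = _coefficients(W, P, q, min(k, a_avail))
            preds[k - 1, mask] = Xte @ B + y_mean
    resid = preds - y[np.newaxis, :]
    return np.sqrt(np.mean(resid * resid, axis=1))


def select_latent_variables(curve: np.ndarray, tol: float = 0.01) -> int:
    """Smallest LV count whose RMSECV is within ``tol`` (relative) of the
    curve minimum; ties resolve to the smaller count."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    if not np.all(np.isfinite(curve)):
        raise ValueError("non-finite RMSECV values")
    threshold = float(curve.min()) * (1.0 + tol)
    return int(np.argmax(curve <= threshold)) + 1


def _split_groups(
    groups: np.ndarray, uniq: np.ndarray, fraction: float,
    rng: np.random.Generator,
) -> list:
    """Choose a seeded batch prefix whose spectrum count best hits the target."""
    perm = uniq[rng.permutation(uniq.size)]
    sizes = np.array([(groups == g).sum() for g in perm])
    cum = np.cumsum(sizes)
    target = fraction * sizes.sum()
    # candidate prefixes leave both sides non-empty
    k = int(np.argmin(np.abs(cum[:-1] - target)))
    return list(perm[: k + 1])


def split_train_test(
    sset: SpectraSet,
    fraction: float = 0.7,
    seed: int = 0,
    group_key: str = "batch_id",
    stratify_key: str | None = None,
) -> tuple[SpectraSet, SpectraSet]:
    """Seeded train/test split by whole batches.

    Whole batches are assigned to one side, targeting the requested
    spectrum-count fraction as closely as batch sizes allow.  Spectra within
    a batch are serially correlated, so a per-spectrum split would overstate
    test performance.  With ``stratify_key`` (e.g. ``site_id``) the split is
    performed within each stratum, so that every instrument keeps roughly the
    same train fraction — a stratum with a single batch goes entirely to the
    training side.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    groups = sset.references[group_key].to_numpy()
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 batches to split")
    rng = np.random.default_rng(seed)
    if stratify_key is None:
        train_groups = _split_groups(groups, uniq, fraction, rng)
    else:
        strat = sset.references[stratify_key].to_numpy()
        strata = {g: strat[groups == g][0] for g in uniq}
        train_groups = []
        for s in sorted({strata[g] for g in uniq}):
            members = np.array([g for g in uniq if strata[g] == s])
            if members.size < 2:
                train_groups.extend(members)
            else:
                train_groups.extend(_split_groups(groups, members, fraction, rng))
    mask = np.isin(groups, train_groups)
    if mask.all() or not mask.any():
        raise ValueError("degenerate split: one side is empty")
    return sset.subset(mask), sset.subset(~mask)
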