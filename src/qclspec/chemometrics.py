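"""Multivariate calibration: preprocessing, NIPALS PLS and cross-validation.

Concentrations are predicted from absorbance spectra with partial
least-squares (PLS) regression.  Latent variables are extracted with the
classical NIPALS recursion, which for a single response reduces to a
deterministic two-line update and for multiple responses iterates the
score/loading pair to convergence from a deterministic start (the response
column with the largest variance).  With as many latent variables as the
rank of the (centred) feature matrix, PLS prediction coincides with
ordinary least squares — a property used as a cross-check in the tests.

Model quality is reported as RMSECV (root-mean-square error of
cross-validation, concentration units) and R^2 on the pooled held-out
predictions, under three fold schemes:

* ``loocv``  — leave-one-measurement-out;
* ``l5ocv``  — leave-5-out: blocks of five consecutive sample ids within
  each measurement series (optionally random blocks);
* ``ldocv``  — leave-one-dataset-out: each fold holds out one full
  measurement series, probing between-series generalisation.

Preprocessing (Savitzky-Golay smoothing, then per-feature standardisation)
is refit on each training fold; held-out spectra are transformed with the
training-fold statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig",
    "PLSModel",
    "CVResult",
    "preprocess",
    "pls_fit",
    "cross_validate",
    "make_folds",
    "rmse",
    "r2",
    "best_result",
]

SCHEMES = ("loocv", "l5ocv", "ldocv")


@dataclass(frozen=True)
class PreprocessConfig:
    savgol_window: int = 9
    savgol_polyorder: int = 2
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.savgol_window % 2 != 1:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.savgol_window <= self.savgol_polyorder:
            raise ValueError("Savitzky-Golay window must exceed the polynomial order")


def preprocess(
    X: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Smooth each spectrum, then centre/scale features with training stats.

    Returns the transformed matrix and the (mean, scale) statistics used.
    Pass the statistics of the training fold when transforming held-out
    spectra so no information leaks across the split.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if config.savgol_window >= X.shape[1]:
        raise ValueError("Savitzky-Golay window is not shorter than the spectrum")
    Xs = savgol_filter(
        X, config.savgol_window, config.savgol_polyorder, axis=1, mode="interp"
    )
    if not config.standardize:
        return Xs, (np.zeros(X.shape[1]), np.ones(X.shape[1]))
    if stats is None:
        mean = Xs.mean(axis=0)
        scale = Xs.std(axis=0, ddof=0)
        # features with negligible variance (< 1e-6 of the dominant feature
        # variance) carry no usable signal; scaling them to unit variance
        # would amplify numerical/discretisation residue into unit-size
        # garbage, so they are left unscaled instead
        floor = 1e-3 * scale.max() if scale.size else 0.0
        scale = np.where(scale > floor, scale, 1.0)
    else:
        mean, scale = stats
    return (Xs - mean) / scale, (mean, scale)


class PLSModel:
    """NIPALS partial least-squares regression with a component path.

    Fitting with ``n_lv`` components also stores the regression coefficients
    for every smaller component count, so cross-validation can score all
    latent-variable choices from one fit.  ``mode='pls1'`` fits one model
    per response column (the default); ``mode='pls2'`` fits a joint model.
    """

    def __init__(self, n_latent_variables: int, mode: str = "pls1"):
        if n_latent_variables < 1:
            raise ValueError("need at least one latent variable")
        if mode not in ("pls1", "pls2"):
            raise ValueError("mode must be 'pls1' or 'pls2'")
        self.n_latent_variables = n_latent_variables
        self.mode = mode
        self.n_achieved_: int | None = None

    # -- single-response NIPALS ------------------------------------------------
    @staticmethod
    def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_comp: int):
        n, p = Xc.shape
        W = np.zeros((p, n_comp))
        P = np.zeros((p, n_comp))
        q = np.zeros(n_comp)
        Xk = Xc.copy()
        yk = yc.copy()
        a = 0
        for a in range(n_comp):
            w = Xk.T @ yk
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                break
            w /= nw
            t = Xk @ w
            tt = t @ t
            if tt < 1e-12:
                break
            p_load = Xk.T @ t / tt
            q_a = yk @ t / tt
            Xk -= np.outer(t, p_load)
            yk -= q_a * t
            W[:, a] = w
            P[:, a] = p_load
            q[a] = q_a
            a += 1
        return W[:, :a], P[:, :a], q[:a], a

    @staticmethod
    def _nipals_pls2(Xc: np.ndarray, Yc: np.ndarray, n_comp: int, max_iter=500, tol=1e-10):
        n, p = Xc.shape
        m = Yc.shape[1]
        W = np.zeros((p, n_comp))
        P = np.zeros((p, n_comp))
        Q = np.zeros((m, n_comp))
        Xk = Xc.copy()
        Yk = Yc.copy()
        a = 0
        for a in range(n_comp):
            j0 = int(np.argmax(Yk.var(axis=0)))
            u = Yk[:, j0].copy()
            if np.linalg.norm(u) < 1e-12:
                break
            t_old = None
            for _ in range(max_iter):
                w = Xk.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-12:
                    break
                w /= nw
                t = Xk @ w
                q_vec = Yk.T @ t / (t @ t)
                u = Yk @ q_vec / (q_vec @ q_vec)
                if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                    break
                t_old = t
            if np.linalg.norm(w) < 1e-12:
                break
            t = Xk @ w
            tt = t @ t
            if tt < 1e-12:
                break
            p_load = Xk.T @ t / tt
            q_vec = Yk.T @ t / tt
            Xk -= np.outer(t, p_load)
            Yk -= np.outer(t, q_vec)
            W[:, a] = w
            P[:, a] = p_load
            Q[:, a] = q_vec
            a += 1
        return W[:, :a], P[:, :a], Q[:, :a], a

    @staticmethod
    def _coef_path(W, P, Q):
        """Regression coefficients for 1..k components: B_k = W_k (P_k' W_k)^-1 Q_k'."""
        k = W.shape[1]
        path = []
        for a in range(1, k + 1):
            Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
            Ba = Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)
            path.append(Ba)
        return path

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        Ym = Y[:, None] if squeeze else Y
        if X.shape[0] != Ym.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        max_lv = min(X.shape[0] - 1, X.shape[1])
        if self.n_latent_variables > max_lv:
            raise ValueError(
                f"n_latent_variables={self.n_latent_variables} exceeds "
                f"min(n_samples-1, n_features)={max_lv}"
            )
        self._squeeze = squeeze
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Ym.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Ym - self.y_mean_

        if self.mode == "pls1":
            # one independent single-response model per column
            paths = []
            achieved = []
            for j in range(Ym.shape[1]):
                W, P, q, a = self._nipals_pls1(Xc, Yc[:, j], self.n_latent_variables)
                paths.append(self._coef_path(W, P, q.reshape(1, -1)))
                achieved.append(a)
            a_min = min(achieved)
            # list over component counts of (p, m) coefficient matrices
            self.coef_path_ = [
                np.column_stack([paths[j][k][:, 0] for j in range(Ym.shape[1])])
                for k in range(a_min)
            ]
            self.n_achieved_ = a_min
        else:
            W, P, Q, a = self._nipals_pls2(Xc, Yc, self.n_latent_variables)
            self.coef_path_ = self._coef_path(W, P, Q)
            self.n_achieved_ = a
        if self.n_achieved_ < self.n_latent_variables:
            warnings.warn(
                f"rank-deficient X: stopped at {self.n_achieved_} of "
                f"{self.n_latent_variables} latent variables",
                stacklevel=2,
            )
        return self

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        k = self.n_achieved_ if n_lv is None else n_lv
        if not 1 <= k <= self.n_achieved_:
            raise ValueError(f"n_lv must lie in [1, {self.n_achieved_}]")
        B = self.coef_path_[k - 1]
        Yp = (X - self.x_mean_) @ B + self.y_mean_
        return Yp[:, 0] if self._squeeze else Yp

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path_[self.n_achieved_ - 1]


def pls_fit(
    X: np.ndarray, Y: np.ndarray, n_lv: int, mode: str = "pls1"
) -> PLSModel:
    """Fit a PLS model with ``n_lv`` latent variables (NIPALS)."""
    return PLSModel(n_lv, mode=mode).fit(X, Y)


def rmse(pred: np.ndarray, ref: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have the same shape")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def r2(pred: np.ndarray, ref: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("pred and ref must share a shape with at least 2 entries")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("reference has zero variance: R^2 undefined")
    ss_res = float(np.sum((ref - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    """Cross-validation summary for one latent-variable count."""

    scheme: str
    n_lv: int
    rmsecv: dict[str, float]  # per-analyte, mg/dL
    r2: dict[str, float]
    fold_assignments: np.ndarray  # fold id per measurement
    predictions: np.ndarray = field(repr=False, default=None)  # (n, q) held-out
    reference: np.ndarray = field(repr=False, default=None)


def make_folds(
    sample_ids: np.ndarray,
    series_ids: np.ndarray,
    scheme: str,
    group_size: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fold id per measurement for the requested scheme."""
    sample_ids = np.asarray(sample_ids)
    series_ids = np.asarray(series_ids)
    if sample_ids.shape != series_ids.shape:
        raise ValueError("sample_ids and series_ids must align")
    n = sample_ids.size
    scheme = scheme.lower()
    if scheme == "loocv":
        return np.arange(n)
    if scheme == "ldocv":
        series = np.unique(series_ids)
        if series.size < 2:
            raise ValueError("leave-one-dataset-out needs at least 2 series")
        lut = {s: k for k, s in enumerate(series)}
        return np.array([lut[s] for s in series_ids])
    if scheme == "l5ocv":
        folds = np.empty(n, dtype=int)
        next_fold = 0
        for s in np.unique(series_ids):
            members = np.flatnonzero(series_ids == s)
            order = members[np.argsort(sample_ids[members], kind="stable")]
            if rng is not None:
                order = rng.permutation(order)
            for start in range(0, order.size, group_size):
                folds[order[start : start + group_size]] = next_fold
                next_fold += 1
        return folds
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    sample_ids: np.ndarray,
    series_ids: np.ndarray,
    scheme: str,
    max_lv: int = 8,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    analyte_names: list[str] | None = None,
    mode: str = "pls1",
    group_size: int = 5,
    rng: np.random.Generator | None = None,
) -> list[CVResult]:
    """RMSECV / R^2 for every latent-variable count from 1 to ``max_lv``.

    Preprocessing statistics and the PLS model are refit on each training
    fold; the returned list holds one :class:`CVResult` per component count,
    scored on the pooled held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    nq = Y.shape[1]
    names = analyte_names or [f"analyte_{j}" for j in range(nq)]
    folds = make_folds(sample_ids, series_ids, scheme, group_size, rng)
    max_train = min(np.sum(folds != f) for f in np.unique(folds)) - 1
    if max_lv > max_train:
        raise ValueError(f"max_lv={max_lv} exceeds training-fold capacity {max_train}")

    preds = np.full((X.shape[0], nq, max_lv), np.nan)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        Xtr, stats = preprocess(X[tr], preprocess_config)
        Xte, _ = preprocess(X[te], preprocess_config, stats=stats)
        model = PLSModel(max_lv, mode=mode).fit(Xtr, Y[tr])
        for k in range(1, model.n_achieved_ + 1):
            preds[te, :, k - 1] = model.predict(Xte, n_lv=k)

    results = []
    for k in range(1, max_lv + 1):
        P = preds[:, :, k - 1]
        if np.any(np.isnan(P)):
            continue  # some fold stopped short of k components
        results.append(
            CVResult(
                scheme=scheme.lower(),
                n_lv=k,
                rmsecv={names[j]: rmse(P[:, j], Y[:, j]) for j in range(nq)},
                r2={names[j]: r2(P[:, j], Y[:, j]) for j in range(nq)},
                fold_assignments=folds,
                predictions=P,
                reference=Y,
            )
        )
    return results


def best_result(results: list[CVResult], analyte: str) -> CVResult:
    """Result with the minimum RMSECV for one analyte (ties: fewer LVs)."""
    if not results:
        raise ValueError("no cross-validation results to choose from")
    return min(results, key=lambda r: (r.rmsecv[analyte], r.n_lv))
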