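"""Model selection relating community predictors to biomass responses.

Three model classes are compared, each selected by leave-one-out
cross-validation (PRESS, the sum of squared out-of-fold prediction errors):

* **A** — ordinary least squares on an exhaustively searched subset of
  community-weighted-mean (CWM) columns;
* **B** — a sign-constrained weighted combination of single-trait Rao
  diversities: for an overall sign ``s`` in {+1, -1}, minimize
  ``sum_i (y_i - a - s * sum_k c_k fd_ik)^2`` subject to ``c_k >= 0``.
  Reported weights are normalized, ``w_k = c_k / sum(c)``, with the overall
  magnitude in ``fd_scale``; a trait with ``c_k = 0`` is unselected;
* **C** — both blocks jointly: unconstrained CWM coefficients and the
  sign-constrained FD block estimated in one convex quadratic program.

The QP is solved exactly by profiling the unconstrained block out
analytically and running non-negative least squares on the projected
residual problem.  Exhaustive class-A search is vectorized over subsets of
equal size; class C crosses a PRESS-ranked shortlist of CWM subsets with the
FD sign (see the package methods note for why the cross is shortlisted).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.optimize import nnls

from .community_metrics import PredictorMatrix

__all__ = [
    "ModelSpec",
    "ModelFit",
    "SignConstraint",
    "loocv_press",
    "fit_model_A",
    "fit_model_B",
    "fit_model_C",
    "partial_r2",
    "replacement_correlations",
]

logger = logging.getLogger(__name__)

_TIE_SIGFIGS = 9  # PRESS values agreeing to 9 significant digits tie exactly

#: Multiplier for the one-standard-error parsimony rule.  Leave-one-out
#: PRESS minimized over many candidate subsets systematically favours
#: supersets (the best of ~16 spurious additions lowers PRESS by several
#: percent almost surely), so candidates whose PRESS lies within
#: ``PRESS_SE_FACTOR`` standard errors of the minimum are treated as tied
#: and ties resolve to the smaller subset, then lexicographic trait order.
#: The standard error is that of the minimizer's PRESS over folds.
PRESS_SE_FACTOR = 1.0


def _press_se(fold_errors: np.ndarray) -> float:
    """Standard error of a PRESS statistic from its per-fold squared errors."""
    d = np.asarray(fold_errors, dtype=float) ** 2
    n = len(d)
    if n < 2:
        return 0.0
    return float(np.sqrt(n * d.var(ddof=1)))


def _banded_sort(items, press_of, size_of, names_of, band):
    """Sort: candidates with PRESS <= band by (size, names), the rest by PRESS."""

    def key(it):
        press = press_of(it)
        if math.isfinite(press) and press <= band:
            return (0, size_of(it), names_of(it), _round_sig(press))
        return (1, _round_sig(press), size_of(it), names_of(it))

    return sorted(items, key=key)


def _parsimony_band(min_press: float, fold_errors: np.ndarray, se_factor: float) -> float:
    if not math.isfinite(min_press):
        return min_press
    return min_press + se_factor * _press_se(fold_errors) + 1e-10 * max(min_press, 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors a model draws on, and the common FD sign."""

    model_class: Literal["A", "B", "C"]
    cwm_traits: tuple[str, ...]
    fd_traits: tuple[str, ...]
    fd_sign: Literal["positive", "negative", "none"]
    max_subset_size: int

    def __post_init__(self) -> None:
        if self.model_class == "A" and self.fd_traits:
            raise ValueError("class A carries no FD traits")
        if self.model_class == "B" and self.cwm_traits:
            raise ValueError("class B carries no CWM traits")
        if (self.fd_sign == "none") != (len(self.fd_traits) == 0):
            raise ValueError("fd_sign is 'none' iff fd_traits is empty")


@dataclass
class ModelFit:
    """A fitted model: coefficients, weights, fit and cross-validation scores."""

    spec: ModelSpec
    intercept: float
    cwm_coefficients: dict[str, float]
    fd_weights: dict[str, float]
    fd_scale: float
    fd_sign: int  # +1 / -1, 0 when no FD block
    r2: float
    loocv_press: float
    partial_r2_cwm: float | None = None
    partial_r2_fd: float | None = None

    def __post_init__(self) -> None:
        if self.fd_weights:
            w = np.array(list(self.fd_weights.values()))
            if np.any(w < -1e-10):
                raise ValueError("negative FD weight")
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("FD weights must sum to 1")
        if not (-1e-10 <= self.r2 <= 1 + 1e-10):
            raise ValueError(f"R^2 out of [0, 1]: {self.r2}")

    def predict(self, predictors: PredictorMatrix) -> np.ndarray:
        yhat = np.full(predictors.n_plots, self.intercept)
        for tr, b in self.cwm_coefficients.items():
            yhat = yhat + b * predictors.cwm[tr].to_numpy()
        for tr, w in self.fd_weights.items():
            yhat = yhat + self.fd_sign * self.fd_scale * w * predictors.fd[tr].to_numpy()
        return yhat


@dataclass(frozen=True)
class SignConstraint:
    """Columns [0, n_unconstrained) free; the rest non-negative times ``sign``."""

    sign: Literal[1, -1]
    n_unconstrained: int = 0


def _round_sig(x: float, sig: int = _TIE_SIGFIGS) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# core solvers
# ---------------------------------------------------------------------------


def _ols_press(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS with intercept: (coefficients incl. intercept, SSE, PRESS).

    PRESS uses the exact hat-matrix shortcut sum((e_i / (1 - h_ii))^2);
    rank-deficient designs fall back to the pseudo-inverse with a warning.
    """
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    G = Z.T @ Z
    try:
        beta = np.linalg.solve(G, Z.T @ y)
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        logger.warning("rank-deficient design; using pseudo-inverse")
        Ginv = np.linalg.pinv(G)
        beta = Ginv @ (Z.T @ y)
    e = y - Z @ beta
    h = np.einsum("ij,jk,ik->i", Z, Ginv, Z)
    denom = 1.0 - h
    if np.any(denom <= 1e-10):
        press = float("inf")
    else:
        press = float(np.sum((e / denom) ** 2))
    return beta, float(e @ e), press


def _ols_fold_errors(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out prediction errors e_i / (1 - h_ii) of an OLS fit."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    G = Z.T @ Z
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    beta = Ginv @ (Z.T @ y)
    e = y - Z @ beta
    h = np.einsum("ij,jk,ik->i", Z, Ginv, Z)
    return e / np.maximum(1.0 - h, 1e-12)


def _constrained_ls(
    X_free: np.ndarray | None,
    F: np.ndarray,
    y: np.ndarray,
    sign: int,
    max_active: int | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact solution of the mixed free / sign-constrained least squares.

    min over (a, b, c >= 0) of ||y - a - X_free b - sign * F c||^2.
    The free block (intercept plus X_free) is profiled out by orthogonal
    projection, leaving a non-negative least-squares problem in c.  FD
    columns are scaled to unit variance internally for conditioning and the
    coefficients back-transformed.  When more than ``max_active`` weights
    come out strictly positive, the problem is re-solved restricted to the
    ``max_active`` largest (standardized-scale) coefficients.
    """
    n = len(y)
    q = 0 if X_free is None or X_free.size == 0 else X_free.shape[1]
    Z = np.column_stack([np.ones(n)] + ([X_free] if q else []))
    Q = orth(Z)
    resid = lambda v: v - Q @ (Q.T @ v)

    sd = F.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Fs = F / sd

    A = sign * np.column_stack([resid(Fs[:, j]) for j in range(Fs.shape[1])])
    yr = resid(y)
    c_s, _ = nnls(A, yr)

    if max_active is not None and int(np.sum(c_s > 0)) > max_active:
        keep = np.argsort(c_s)[::-1][:max_active]
        c_restricted = np.zeros_like(c_s)
        sub, _ = nnls(A[:, keep], yr)
        c_restricted[keep] = sub
        c_s = c_restricted

    c = c_s / sd
    free_coef, *_ = np.linalg.lstsq(Z, y - sign * F @ c, rcond=None)
    intercept = float(free_coef[0])
    b = free_coef[1:] if q else np.zeros(0)
    return intercept, b, c


def _press_constrained(
    X_free: np.ndarray | None,
    F: np.ndarray,
    y: np.ndarray,
    sign: int,
    max_active: int | None = None,
) -> tuple[float, np.ndarray]:
    """Explicit leave-one-out PRESS (and fold errors) of the constrained fit."""
    n = len(y)
    idx = np.arange(n)
    errors = np.empty(n)
    for i in range(n):
        m = idx != i
        Xf = X_free[m] if X_free is not None and X_free.size else None
        a, b, c = _constrained_ls(Xf, F[m], y[m], sign, max_active)
        pred = a + sign * float(F[i] @ c)
        if X_free is not None and X_free.size:
            pred += float(X_free[i] @ b)
        errors[i] = y[i] - pred
    return float(errors @ errors), errors


def loocv_press(
    design_matrix: np.ndarray | pd.DataFrame,
    response: np.ndarray | Sequence[float],
    constraint: SignConstraint | None = None,
) -> float:
    """Leave-one-out PRESS of a linear model with intercept.

    Unconstrained fits use the exact hat-matrix shortcut; under a
    :class:`SignConstraint` every fold is refit explicitly with the same
    constraints.
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    p = X.shape[1] if X.ndim == 2 else 1
    if n <= p + 1:
        raise ValueError("loocv_press requires n plots > predictors + 1")
    if constraint is None:
        _, _, press = _ols_press(X, y)
        return press
    q = constraint.n_unconstrained
    Xf = X[:, :q] if q else None
    F = X[:, q:]
    press, _ = _press_constrained(Xf, F, y, constraint.sign, None)
    return press


# ---------------------------------------------------------------------------
# class A: exhaustive CWM best-subset
# ---------------------------------------------------------------------------


def _search_cwm_subsets(
    Xc: np.ndarray,
    yc: np.ndarray,
    max_size: int,
    chunk: int = 4096,
) -> list[tuple[float, tuple[int, ...]]]:
    """Evaluate LOOCV PRESS of every CWM subset up to ``max_size``.

    Operates on column-centered predictors and response; the intercept is
    implicit (leverage gains the 1/n term of the uncentered fit).  Subsets of
    one size are evaluated in vectorized batches.  Returns (press, subset)
    pairs sorted by (tied PRESS, size, subset indices).
    """
    n, p = Xc.shape
    XT = Xc.T.copy()
    records: list[tuple[float, tuple[int, ...]]] = []

    # size 0: intercept-only
    h0 = 1.0 / n
    press0 = float(np.sum((yc / (1.0 - h0)) ** 2))
    records.append((press0, ()))

    for k in range(1, max_size + 1):
        combos = np.array(list(itertools.combinations(range(p), k)), dtype=int)
        for a in range(0, len(combos), chunk):
            I = combos[a : a + chunk]
            Xs = XT[I]  # (c, k, n)
            G = Xs @ Xs.transpose(0, 2, 1)
            rhs = Xs @ yc
            try:
                beta = np.linalg.solve(G, rhs[..., None])[..., 0]
                Ginv = np.linalg.inv(G)
            except np.linalg.LinAlgError:
                beta = np.empty_like(rhs)
                Ginv = np.empty_like(G)
                for j in range(len(I)):
                    Gj = np.linalg.pinv(G[j])
                    Ginv[j] = Gj
                    beta[j] = Gj @ rhs[j]
                logger.warning("rank-deficient subset(s) at size %d; pseudo-inverse", k)
            fitted = np.einsum("ckn,ck->cn", Xs, beta)
            r = yc[None, :] - fitted
            T = np.einsum("ckj,cjn->ckn", Ginv, Xs)
            h = 1.0 / n + np.einsum("ckn,ckn->cn", Xs, T)
            denom = 1.0 - h
            bad = (denom <= 1e-10).any(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                press = np.sum((r / denom) ** 2, axis=1)
            press[bad] = np.inf
            for j in range(len(I)):
                records.append((float(press[j]), tuple(int(v) for v in I[j])))

    records.sort(key=lambda rec: (_round_sig(rec[0]), len(rec[1]), rec[1]))
    return records


def _guard_subset_size(max_subset_size: int, n: int) -> None:
    if max_subset_size >= n / 2:
        raise ValueError(
            f"max_subset_size {max_subset_size} >= n/2 = {n / 2:.0f}: refusing "
            "to search subsets that large (overfitting guard)"
        )


def _r2(sse: float, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return min(max(1.0 - sse / sst, 0.0), 1.0)


def fit_model_A(
    predictors: PredictorMatrix,
    response: np.ndarray | Sequence[float],
    max_subset_size: int = 8,
    top: int = 3,
    se_factor: float = PRESS_SE_FACTOR,
) -> tuple[ModelFit, list[ModelFit]]:
    """Exhaustive CWM best-subset OLS ranked by LOOCV PRESS.

    Every subset of CWM columns of size 0..max_subset_size is fit by ordinary
    least squares and ranked by PRESS ascending under the one-standard-error
    parsimony rule: subsets whose PRESS lies within ``se_factor`` standard
    errors of the minimum count as tied, and ties resolve to the smaller
    subset, then lexicographic trait order.  Returns the winner and the
    ``top`` best fits.
    """
    y = np.asarray(response, dtype=float)
    n = predictors.n_plots
    if len(y) != n:
        raise ValueError("response length does not match predictor rows")
    _guard_subset_size(max_subset_size, n)

    abbrevs = list(predictors.cwm.columns)
    X = predictors.cwm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    records = _search_cwm_subsets(Xc, yc, max_subset_size)
    min_rec = min(records, key=lambda rec: rec[0])
    band = _parsimony_band(
        min_rec[0],
        _ols_fold_errors(X[:, list(min_rec[1])], y),
        se_factor,
    )
    records = _banded_sort(
        records,
        press_of=lambda rec: rec[0],
        size_of=lambda rec: len(rec[1]),
        names_of=lambda rec: tuple(sorted(abbrevs[i] for i in rec[1])),
        band=band,
    )

    fits = [
        _refit_A(predictors, y, rec[1], rec[0], max_subset_size)
        for rec in records[: max(top, 1)]
    ]
    return fits[0], fits


def _refit_A(
    predictors: PredictorMatrix,
    y: np.ndarray,
    subset: tuple[int, ...],
    press: float,
    max_subset_size: int,
) -> ModelFit:
    abbrevs = list(predictors.cwm.columns)
    names = tuple(abbrevs[i] for i in subset)
    X = predictors.cwm.to_numpy(dtype=float)[:, list(subset)]
    beta, sse, _ = _ols_press(X, y)
    spec = ModelSpec(
        model_class="A",
        cwm_traits=names,
        fd_traits=(),
        fd_sign="none",
        max_subset_size=max_subset_size,
    )
    return ModelFit(
        spec=spec,
        intercept=float(beta[0]),
        cwm_coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        fd_weights={},
        fd_scale=0.0,
        fd_sign=0,
        r2=_r2(sse, y),
        loocv_press=press,
    )


# ---------------------------------------------------------------------------
# class B: sign-constrained FD weights
# ---------------------------------------------------------------------------


def _fit_fd_block(
    predictors: PredictorMatrix,
    y: np.ndarray,
    sign: int,
    max_subset_size: int,
    X_free: np.ndarray | None = None,
    cwm_names: tuple[str, ...] = (),
    model_class: str = "B",
) -> ModelFit | None:
    """Fit one sign of the constrained FD model (optionally with a CWM block)."""
    F = predictors.fd.to_numpy(dtype=float)
    abbrevs = list(predictors.fd.columns)
    a, b, c = _constrained_ls(X_free, F, y, sign, max_subset_size)
    active = np.flatnonzero(c > 0)
    if len(active) == 0 and model_class == "B":
        return None
    press, fold_errors = _press_constrained(X_free, F, y, sign, max_subset_size)
    yhat = a + sign * F @ c
    if X_free is not None and X_free.size:
        yhat = yhat + X_free @ b
    sse = float(np.sum((y - yhat) ** 2))
    total = float(c.sum())
    fd_names = tuple(abbrevs[i] for i in active)
    weights = (
        {abbrevs[i]: float(c[i] / total) for i in active} if total > 0 else {}
    )
    spec = ModelSpec(
        model_class=model_class,  # type: ignore[arg-type]
        cwm_traits=cwm_names,
        fd_traits=fd_names if weights else (),
        fd_sign=("positive" if sign > 0 else "negative") if weights else "none",
        max_subset_size=max_subset_size,
    )
    fit = ModelFit(
        spec=spec,
        intercept=float(a),
        cwm_coefficients={nm: float(v) for nm, v in zip(cwm_names, b)},
        fd_weights=weights,
        fd_scale=total,
        fd_sign=sign if weights else 0,
        r2=_r2(sse, y),
        loocv_press=press,
    )
    fit._fold_errors = fold_errors  # for the 1-SE parsimony band
    return fit


def _intercept_only_fit(
    y: np.ndarray, max_subset_size: int, model_class: str = "B"
) -> ModelFit:
    _, sse, press = _ols_press(np.zeros((len(y), 0)), y)
    spec = ModelSpec(
        model_class=model_class,  # type: ignore[arg-type]
        cwm_traits=(),
        fd_traits=(),
        fd_sign="none",
        max_subset_size=max_subset_size,
    )
    fit = ModelFit(
        spec=spec,
        intercept=float(np.mean(y)),
        cwm_coefficients={},
        fd_weights={},
        fd_scale=0.0,
        fd_sign=0,
        r2=0.0,
        loocv_press=press,
    )
    fit._fold_errors = _ols_fold_errors(np.zeros((len(y), 0)), y)
    return fit


def fit_model_B(
    predictors: PredictorMatrix,
    response: np.ndarray | Sequence[float],
    max_subset_size: int = 8,
    top: int = 3,
    se_factor: float = PRESS_SE_FACTOR,
) -> tuple[ModelFit, list[ModelFit]]:
    """Sign-constrained weighted FD_Q model, one common sign per model.

    Both overall signs are fit by the exact QP; the candidate list (positive
    fit, negative fit, intercept-only) is ranked by LOOCV PRESS.  If neither
    sign selects any trait the intercept-only fit is returned with a warning.
    """
    y = np.asarray(response, dtype=float)
    n = predictors.n_plots
    if len(y) != n:
        raise ValueError("response length does not match predictor rows")
    _guard_subset_size(max_subset_size, n)

    candidates: list[ModelFit] = []
    for sign in (1, -1):
        fit = _fit_fd_block(predictors, y, sign, max_subset_size)
        if fit is not None:
            candidates.append(fit)
    if not candidates:
        warnings.warn(
            "no FD trait selected under either sign; returning intercept-only fit",
            stacklevel=2,
        )
        fit0 = _intercept_only_fit(y, max_subset_size)
        return fit0, [fit0]
    candidates.append(_intercept_only_fit(y, max_subset_size))
    min_fit = min(candidates, key=lambda f: f.loocv_press)
    band = _parsimony_band(min_fit.loocv_press, min_fit._fold_errors, se_factor)
    candidates = _banded_sort(
        candidates,
        press_of=lambda f: f.loocv_press,
        size_of=lambda f: len(f.spec.fd_traits),
        names_of=lambda f: tuple(sorted(f.spec.fd_traits)),
        band=band,
    )
    return candidates[0], candidates[:top]


# ---------------------------------------------------------------------------
# class C: joint CWM + sign-constrained FD
# ---------------------------------------------------------------------------


def fit_model_C(
    predictors: PredictorMatrix,
    response: np.ndarray | Sequence[float],
    max_subset_size: int = 8,
    top: int = 3,
    n_cwm_candidates: int = 20,
    se_factor: float = PRESS_SE_FACTOR,
) -> tuple[ModelFit, list[ModelFit]]:
    """Joint CWM (unconstrained) + FD (sign-constrained) model selection.

    CWM candidate subsets are the ``n_cwm_candidates`` best class-A subsets
    by LOOCV PRESS (including the empty subset if it ranks); each is crossed
    with FD sign in {positive, negative, none} and the joint QP refit, all
    ranked by LOOCV PRESS.  With no FD candidates selected the fit reduces
    exactly to the class-A OLS fit on that subset.
    """
    y = np.asarray(response, dtype=float)
    n = predictors.n_plots
    if len(y) != n:
        raise ValueError("response length does not match predictor rows")
    _guard_subset_size(max_subset_size, n)

    abbrevs = list(predictors.cwm.columns)
    X = predictors.cwm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    records = _search_cwm_subsets(Xc, yc, max_subset_size)
    records.sort(
        key=lambda rec: (
            _round_sig(rec[0]),
            len(rec[1]),
            tuple(sorted(abbrevs[i] for i in rec[1])),
        )
    )
    shortlist = records[:n_cwm_candidates]
    if () not in {rec[1] for rec in shortlist}:
        shortlist.append(next(rec for rec in records if rec[1] == ()))

    candidates: list[ModelFit] = []
    for press_a, subset in shortlist:
        names = tuple(abbrevs[i] for i in subset)
        Xs = X[:, list(subset)] if subset else None
        # sign 'none': the plain class-A fit on this subset, relabelled C
        fit_a = _refit_A(predictors, y, subset, press_a, max_subset_size)
        candidates.append(
            ModelFit(
                spec=ModelSpec(
                    model_class="C",
                    cwm_traits=names,
                    fd_traits=(),
                    fd_sign="none",
                    max_subset_size=max_subset_size,
                ),
                intercept=fit_a.intercept,
                cwm_coefficients=fit_a.cwm_coefficients,
                fd_weights={},
                fd_scale=0.0,
                fd_sign=0,
                r2=fit_a.r2,
                loocv_press=press_a,
            )
        )
        for sign in (1, -1):
            fit = _fit_fd_block(
                predictors,
                y,
                sign,
                max_subset_size,
                X_free=Xs,
                cwm_names=names,
                model_class="C",
            )
            if fit is not None:
                candidates.append(fit)

    min_fit = min(candidates, key=lambda f: f.loocv_press)
    if hasattr(min_fit, "_fold_errors"):
        fold_errors = min_fit._fold_errors
    else:  # a 'none'-sign candidate from the batched OLS search
        fold_errors = _ols_fold_errors(
            X[:, [abbrevs.index(t) for t in min_fit.spec.cwm_traits]], y
        )
    band = _parsimony_band(min_fit.loocv_press, fold_errors, se_factor)
    candidates = _banded_sort(
        candidates,
        press_of=lambda f: f.loocv_press,
        size_of=lambda f: len(f.spec.cwm_traits) + len(f.spec.fd_traits),
        names_of=lambda f: tuple(sorted(f.spec.cwm_traits + f.spec.fd_traits)),
        band=band,
    )
    best = candidates[0]
    pr_cwm, pr_fd = partial_r2(best, predictors, y)
    best.partial_r2_cwm, best.partial_r2_fd = pr_cwm, pr_fd
    return best, candidates[:top]


def replacement_correlations(
    ranked: Sequence[ModelFit],
    predictors: PredictorMatrix,
) -> pd.DataFrame:
    """Diagnostic: how closely related are traits swapped between top models.

    For each trait appearing in the best model's CWM set but absent from a
    runner-up, reports the rank (1 = most correlated) of its best substitute
    among the runner-up's new traits in the |correlation| ordering of all
    candidate CWM columns.  Near-rank-1 replacements indicate that model
    selection is stable up to swaps of closely related traits.
    """
    if not ranked:
        return pd.DataFrame(columns=["model_rank", "dropped", "replacement", "corr_rank"])
    C = predictors.cwm.corr().abs()
    best = set(ranked[0].spec.cwm_traits)
    rows = []
    for r, fit in enumerate(ranked[1:], start=2):
        other = set(fit.spec.cwm_traits)
        dropped, added = best - other, other - best
        for tr in dropped:
            order = C[tr].drop(tr).sort_values(ascending=False)
            for sub in added:
                rows.append(
                    {
                        "model_rank": r,
                        "dropped": tr,
                        "replacement": sub,
                        "corr_rank": int(order.index.get_loc(sub)) + 1,
                    }
                )
    return pd.DataFrame(rows, columns=["model_rank", "dropped", "replacement", "corr_rank"])


def partial_r2(
    fit: ModelFit,
    predictors: PredictorMatrix,
    response: np.ndarray | Sequence[float],
) -> tuple[float, float]:
    """Marginal-group R^2: each selected block refit alone.

    ``partial_r2_cwm`` is the in-sample R^2 of an OLS refit on the fit's
    selected CWM traits; ``partial_r2_fd`` the R^2 of the sign-constrained
    refit on its selected FD traits under the fitted sign.  An empty block
    reports 0.  The two need not sum to the joint R^2.
    """
    y = np.asarray(response, dtype=float)
    if fit.spec.cwm_traits:
        Xs = predictors.cwm[list(fit.spec.cwm_traits)].to_numpy(dtype=float)
        _, sse, _ = _ols_press(Xs, y)
        pr_cwm = _r2(sse, y)
    else:
        pr_cwm = 0.0
    if fit.spec.fd_traits:
        F = predictors.fd[list(fit.spec.fd_traits)].to_numpy(dtype=float)
        sign = fit.fd_sign if fit.fd_sign else 1
        a, _, c = _constrained_ls(None, F, y, sign, None)
        sse = float(np.sum((y - a - sign * F @ c) ** 2))
        pr_fd = _r2(sse, y)
    else:
        pr_fd = 0.0
    return pr_cwm, pr_fd
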