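"""PLS2 multivariate calibration via NIPALS.

The classical nonlinear iterative partial least squares algorithm, written
from first principles: latent variables are extracted one at a time as
score/weight/loading tuples maximizing X-Y covariance, with deflation of
both blocks. Model selection uses leave-one-out cross-validation: a
root-mean-square-error-of-cross-validation (RMSECV) curve over candidate
latent-variable counts and a parsimony rule that picks the smallest count
whose RMSECV is within a fixed fraction of the curve minimum.

Everything operates on raw (uncentered) matrices; the fitted model stores
and reapplies the calibration-set column means, so predictions are on the
original concentration scale (ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (
    CenteringTransform,
    apply_centering,
    fit_centering,
    invert_centering,
)

_CONV_TOL = 1e-12
_MAX_ITER = 500
_RANK_EPS = 1e-12


@dataclass(frozen=True)
class PlsModel:
    """Fitted PLS2 model.

    W: X-weights (wavelengths x A), P: X-loadings, Q: Y-loadings
    (components x A), B: regression coefficients (wavelengths x components)
    acting on centered spectra, n_lv: number of latent variables A.
    """

    centering: CenteringTransform
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    n_lv: int
    scores: np.ndarray  # calibration scores T (n x A), kept for diagnostics


@dataclass(frozen=True)
class CvCurve:
    """Leave-one-out error versus latent-variable count (1..A_max)."""

    n_lv: np.ndarray
    rmsecv: np.ndarray  # pooled over samples and components, original units
    rmsecv_per_component: np.ndarray  # A_max x n_components
    rmsec: np.ndarray  # calibration-set (refit) error, same pooling

    def __post_init__(self) -> None:
        if not (len(self.n_lv) == len(self.rmsecv) == len(self.rmsec)
                == self.rmsecv_per_component.shape[0]):
            raise ValueError("inconsistent curve lengths")
        if np.any(self.rmsecv < 0) or np.any(self.rmsec < 0):
            raise ValueError("errors must be non-negative")


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_lv: int):
    """Extract n_lv components from centered blocks; returns W, P, Q, T."""
    n, p = Xc.shape
    m = Yc.shape[1]
    X = Xc.copy()
    Y = Yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    x_scale = np.linalg.norm(Xc) or 1.0
    for a in range(n_lv):
        if np.linalg.norm(X) <= _RANK_EPS * x_scale:
            raise ValueError(
                f"X block exhausted after {a} latent variables; "
                f"requested {n_lv}, achievable maximum is {a}"
            )
        # deterministic start: Y column of maximal residual variance
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        if np.linalg.norm(u) == 0.0:
            u = X[:, np.argmax(X.var(axis=0))].copy()
        w = np.zeros(p)
        for _ in range(_MAX_ITER):
            w_new = X.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0.0:
                raise ValueError(
                    f"degenerate weight vector at latent variable {a + 1}; "
                    f"achievable maximum is {a}"
                )
            w_new /= nw
            if np.linalg.norm(w_new - w) <= _CONV_TOL:
                w = w_new
                break
            w = w_new
            t = X @ w
            q = Y.T @ t / (t @ t)
            if np.linalg.norm(q) == 0.0:
                break
            u = Y @ q / (q @ q)
        # fixed sign convention: largest-|w| element positive
        imax = np.argmax(np.abs(w))
        if w[imax] < 0:
            w = -w
        t = X @ w
        tt = t @ t
        if tt <= _RANK_EPS * x_scale**2:
            raise ValueError(
                f"rank deficient at latent variable {a + 1}; "
                f"achievable maximum is {a}"
            )
        p_vec = X.T @ t / tt
        q_vec = Y.T @ t / tt
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q_vec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q_vec, t
    return W, P, Q, T


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int) -> PlsModel:
    """Fit a PLS2 model with ``n_lv`` latent variables on raw matrices.

    Centering of both blocks is fitted internally on (X, Y) and stored in
    the model. Deterministic: fixed initialization and sign convention.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    a_cap = min(X.shape[0] - 1, X.shape[1])
    if n_lv > a_cap:
        raise ValueError(
            f"n_lv={n_lv} exceeds min(n_samples-1, n_wavelengths)={a_cap}"
        )
    centering = fit_centering(X, Y)
    Xc = apply_centering(centering, X, kind="x")
    Yc = apply_centering(centering, Y, kind="y")
    W, P, Q, T = _nipals(Xc, Yc, n_lv)
    # B maps centered X to centered Y: B = W (P'W)^-1 Q'
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PlsModel(centering=centering, W=W, P=P, Q=Q, B=B, n_lv=n_lv, scores=T)


def predict_pls(model: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations for raw spectra using the stored centering."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.centering.n_x:
        raise ValueError(
            f"X_new has {X_new.shape[1]} wavelengths, model expects "
            f"{model.centering.n_x}"
        )
    Xc = apply_centering(model.centering, X_new, kind="x")
    Yc = Xc @ model.B
    return invert_centering(model.centering, Yc, kind="y")


def loo_curve(X: np.ndarray, Y: np.ndarray, a_max: int) -> CvCurve:
    """Leave-one-out RMSECV (and refit RMSEC) for A = 1..a_max.

    Every sample is predicted by a model fitted on the remaining n-1; errors
    are pooled over samples and components on the original concentration
    scale. The per-fold rank limit n-2 must admit a_max.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    n, m = Y.shape
    fold_cap = min(n - 2, X.shape[1])
    if not 1 <= a_max <= fold_cap:
        raise ValueError(
            f"a_max must be in 1..{fold_cap} for {n} samples, got {a_max}"
        )
    press = np.zeros((a_max, m))  # squared LOO residuals per component
    for i in range(n):
        keep = np.arange(n) != i
        pred = None
        for a in range(1, a_max + 1):
            # a fold may be rank-exhausted below a_max (e.g. noiseless
            # low-rank spectra); reuse the deepest feasible model then
            try:
                model = fit_pls(X[keep], Y[keep], a)
                pred = predict_pls(model, X[i][None, :])
            except ValueError:
                if pred is None:
                    raise
            press[a - 1] += (pred[0] - Y[i]) ** 2
    rmsecv_pc = np.sqrt(press / n)
    rmsecv = np.sqrt(press.sum(axis=1) / (n * m))
    rmsec = np.empty(a_max)
    last = None
    for a in range(1, a_max + 1):
        try:
            model = fit_pls(X, Y, a)
            resid = predict_pls(model, X) - Y
            last = np.sqrt(np.mean(resid**2))
        except ValueError:
            if last is None:
                raise
        rmsec[a - 1] = last
    return CvCurve(
        n_lv=np.arange(1, a_max + 1),
        rmsecv=rmsecv,
        rmsecv_per_component=rmsecv_pc,
        rmsec=rmsec,
    )


def select_n_lv(curve: CvCurve, threshold_ratio: float = 0.02) -> int:
    """Smallest A whose RMSECV is within (1 + threshold_ratio) of the minimum.

    A parsimony rule standing in for the usual visual judgement of the
    error-versus-complexity plot; threshold_ratio=0 returns the argmin
    (earliest on ties).
    """
    if len(curve.rmsecv) == 0:
        raise ValueError("empty curve")
    cutoff = (1.0 + threshold_ratio) * curve.rmsecv.min()
    idx = int(np.flatnonzero(curve.rmsecv <= cutoff)[0])
    return int(curve.n_lv[idx])
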