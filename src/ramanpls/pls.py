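"""Partial least squares regression (NIPALS, PLS2) with latent-variable
selection by cross-validated parsimony.

The calibration problem is small (10 tablets, a few hundred derivative
features, 3 responses), so the classical NIPALS algorithm with mean
centering and successive deflation is used.  One model serves the three
polymorph responses jointly (PLS2); fitting one model per response (PLS1)
is available by passing single-column Y matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Convergence tolerance on the weight vector between NIPALS iterations.
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500

#: A component whose score norm falls below this fraction of the centered-X
#: norm is treated as rank exhaustion.
_RANK_EPS = 1e-12


@dataclass
class PlsModel:
    """A fitted PLS regression model.

    Attributes
    ----------
    n_lv : number of latent variables actually extracted.
    x_mean, y_mean : training column means used for centering.
    weights, x_loadings, y_loadings : per-LV vectors (columns), shapes
        (p, n_lv), (p, n_lv), (q, n_lv).
    x_variance_explained : % of centered-X sum of squares per LV.
    interval_set : wavenumber intervals the model was fit on (metadata).
    preprocess : preprocessing parameters (metadata).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_variance_explained: np.ndarray
    scores: np.ndarray | None = None
    interval_set: list[tuple[float, float]] | None = None
    preprocess: object | None = None
    _coef_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_features(self) -> int:
        return int(self.x_mean.size)

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression coefficient matrix B (p x q) using the first ``n_lv`` LVs."""
        k = self.n_lv if n_lv is None else min(int(n_lv), self.n_lv)
        if k < 1:
            raise ValueError("n_lv must be >= 1")
        if k not in self._coef_cache:
            W, P, Q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
            # B = W (P^T W)^{-1} Q^T; P^T W is upper triangular and well
            # conditioned for NIPALS deflation.
            self._coef_cache[k] = W @ np.linalg.solve(P.T @ W, Q.T)
        return self._coef_cache[k]

    @property
    def cumulative_x_variance(self) -> np.ndarray:
        return np.cumsum(self.x_variance_explained)


@dataclass(frozen=True)
class CvResult:
    """Leave-one-out RMSECV as a function of the candidate LV count."""

    lv_candidates: tuple[int, ...]
    rmsecv_per_response: np.ndarray  # (n_candidates, n_responses), CBZ-mass-% units
    rmsecv_mean: np.ndarray  # (n_candidates,), averaged over responses
    chosen_n_lv: int | None = None

    def with_choice(self, n_lv: int) -> "CvResult":
        if n_lv not in self.lv_candidates:
            raise ValueError(f"chosen n_lv {n_lv} not among candidates {self.lv_candidates}")
        return CvResult(self.lv_candidates, self.rmsecv_per_response, self.rmsecv_mean, n_lv)


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int, **meta) -> PlsModel:
    """Fit a PLS2 regression of Y on X with ``n_lv`` latent variables.

    X and Y are column-centered internally; no variance scaling is applied
    (derivative spectra share units, and interval selection is deliberately
    scale-sensitive).  If the centered X runs out of rank before ``n_lv``
    components, extraction stops early with a warning and the model reports
    the actual count.

    Parameters
    ----------
    X : (n, p) feature matrix.
    Y : (n, q) response matrix, here polymorph content in % of total CBZ mass.
    n_lv : requested number of latent variables (>= 1).
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if Y.shape[0] != n:
        raise ValueError("X and Y sample counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    max_lv = min(n - 1, p)
    if not (1 <= n_lv <= max_lv):
        raise ValueError(f"n_lv must be in [1, {max_lv}] for this instance, got {n_lv}")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    total_ss = float(np.sum(Xc**2))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    xvar = np.zeros(n_lv)

    a = 0
    for a in range(n_lv):
        if np.sum(Xc**2) <= _RANK_EPS * max(total_ss, 1.0):
            warnings.warn(
                f"rank exhausted after {a} latent variables (requested {n_lv})",
                stacklevel=2,
            )
            break
        # start from the Y column with the largest residual variance
        u = Yc[:, np.argmax(np.sum(Yc**2, axis=0))].copy()
        if np.sum(u**2) <= _RANK_EPS * max(float(np.sum(Y**2)), 1.0):
            # Y residual is (numerically) zero: nothing left to model
            break
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = Xc @ w_new
            tt = float(t @ t)
            if tt == 0:
                break
            q = Yc.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                break
            u = Yc @ q / qq
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _RANK_EPS * max(total_ss, 1.0):
            warnings.warn(
                f"rank exhausted after {a} latent variables (requested {n_lv})",
                stacklevel=2,
            )
            break
        pvec = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
        xvar[a] = 100.0 * tt * float(pvec @ pvec) / total_ss if total_ss > 0 else 0.0
        a += 1

    actual = a
    if actual == 0:
        # degenerate: constant Y (or zero-rank X) -> intercept-only model
        W = np.zeros((p, 1))
        P = np.zeros((p, 1))
        Q = np.zeros((Y.shape[1], 1))
        T = np.zeros((n, 1))
        model = PlsModel(
            n_lv=1, x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
            y_loadings=Q, x_variance_explained=np.zeros(1), scores=T, **meta,
        )
        model._coef_cache[1] = np.zeros((p, Y.shape[1]))
        return model
    return PlsModel(
        n_lv=actual,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :actual],
        x_loadings=P[:, :actual],
        y_loadings=Q[:, :actual],
        x_variance_explained=xvar[:actual],
        scores=T[:, :actual],
        **meta,
    )


def predict(model: PlsModel, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predict responses for new feature rows: ``(x - x_mean) B + y_mean``.

    Predictions are deliberately not clipped to [0, 100] and not forced to
    sum to 100; the calibration scatter about the identity line is left
    unconstrained.
    """
    X_new = np.asarray(X_new, dtype=float)
    one_row = X_new.ndim == 1
    if one_row:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match model ({model.n_features})"
        )
    Y_hat = (X_new - model.x_mean) @ model.coefficients(n_lv) + model.y_mean
    return Y_hat[0] if one_row else Y_hat


def explained_x_variance(model: PlsModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-LV and cumulative % of centered-X sum of squares captured."""
    per_lv = model.x_variance_explained.copy()
    return per_lv, np.cumsum(per_lv)


def choose_n_lv(cv: CvResult, improvement_threshold: float = 0.05) -> int:
    """Parsimonious LV count from an RMSECV curve.

    Returns the smallest k such that adding the (k+1)-th latent variable
    improves the response-averaged RMSECV by less than
    ``improvement_threshold`` (relative), guarding against over-fitted
    models with an excess of latent variables.  A curve entry of exactly
    zero stops the search (no relative improvement is possible).
    """
    curve = np.asarray(cv.rmsecv_mean, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    k = 0
    while k + 1 < curve.size:
        if curve[k] <= 0:
            break
        if (curve[k] - curve[k + 1]) / curve[k] < improvement_threshold:
            break
        k += 1
    return int(cv.lv_candidates[k])
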