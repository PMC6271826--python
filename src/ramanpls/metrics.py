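"""Error metrics, the leave-one-out cross-validation driver, mass-basis
conversion and the tabular error report.

All primary errors are root-mean-square errors,

    RMSE = sqrt( sum_i (y_i - yhat_i)^2 / n ),

computed on the calibration fits (RMSEC), the leave-one-out held-out
predictions (RMSECV) and the external validation predictions (RMSEV).
Concentrations are % of total carbamazepine mass; multiplying by the CBZ
mass fraction of the tablet (nominally 50/300) converts an error to the
whole-tablet basis, the figure a quality-control lab quotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .pls import CvResult, fit_pls, predict
from .synthetic import POLYMORPHS

logger = logging.getLogger(__name__)

_METRICS = ("rmsec", "rmsecv", "rmsev")


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error between true and predicted concentrations."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    if y.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("R^2 is undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def convert_basis(error_cbz_pct: float, cbz_tablet_fraction: float) -> float:
    """Convert an error from the CBZ-mass basis to the tablet-mass basis.

    A 9.49% error on 16.67% of the tablet is a 1.58% error on the whole
    tablet; the conversion is the plain product.
    """
    if not (0.0 < cbz_tablet_fraction <= 1.0):
        raise ValueError("cbz_tablet_fraction must be in (0, 1]")
    if error_cbz_pct < 0:
        raise ValueError("error must be >= 0")
    return error_cbz_pct * cbz_tablet_fraction


def loo_cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    lv_candidates: int | list[int] | tuple[int, ...],
) -> tuple[CvResult, np.ndarray]:
    """Leave-one-out cross-validation of a PLS model.

    Each sample in turn is withheld; the model is refit on the remaining
    samples (re-centering inside the fold, so no information leaks from the
    held-out row) and the withheld sample predicted.  If a fold's rank
    cannot support the requested LV count the fold uses as many components
    as it has (logged), mirroring rank-exhaustion in the fitter.

    Returns the :class:`~ramanpls.pls.CvResult` (RMSECV per candidate LV
    count, per response and response-averaged) and the held-out prediction
    array of shape (n_candidates, n, q).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if isinstance(lv_candidates, (int, np.integer)):
        candidates: tuple[int, ...] = (int(lv_candidates),)
    else:
        candidates = tuple(int(k) for k in lv_candidates)
    if not candidates:
        raise ValueError("no LV candidates")
    fold_cap = min(n - 2, X.shape[1])
    candidates = tuple(k for k in candidates if 1 <= k <= fold_cap)
    if not candidates:
        raise ValueError(
            f"no LV candidate fits the fold size/feature count (cap {fold_cap})"
        )
    max_lv = max(candidates)

    preds = np.empty((len(candidates), n, Y.shape[1]))
    import warnings as _warnings

    for i in range(n):
        keep = np.arange(n) != i
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # rank exhaustion handled below
            model = fit_pls(X[keep], Y[keep], n_lv=max_lv)
        if model.n_lv < max_lv:
            logger.info(
                "LOO fold %d: rank supports only %d of %d latent variables",
                i, model.n_lv, max_lv,
            )
        for j, k in enumerate(candidates):
            preds[j, i] = predict(model, X[i], n_lv=min(k, model.n_lv))

    per_resp = np.sqrt(np.mean((preds - Y[None]) ** 2, axis=1))  # (cand, q)
    mean = per_resp.mean(axis=1)
    return CvResult(candidates, per_resp, mean), preds


@dataclass
class ErrorReport:
    """Per-polymorph error table on both mass bases.

    ``table`` has one row per polymorph and columns ``rmsec``, ``rmsecv``,
    ``rmsev`` (CBZ-mass basis, % wt/wt), their ``*_tablet`` counterparts
    (tablet-mass basis), ``r2`` pooled over calibration + validation, and
    ``r2_cal``/``r2_val`` for transparency.  Full precision is stored; the
    formatted rendering rounds to 2 decimals.
    """

    table: pd.DataFrame
    n_cal: int
    n_val: int
    cbz_tablet_fraction: float
    meta: dict = field(default_factory=dict)

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf, index=True, index_label="polymorph")

    @classmethod
    def from_csv(cls, path_or_buf, n_cal: int = 0, n_val: int = 0,
                 cbz_tablet_fraction: float = float("nan")) -> "ErrorReport":
        table = pd.read_csv(path_or_buf, index_col="polymorph")
        return cls(table=table, n_cal=n_cal, n_val=n_val,
                   cbz_tablet_fraction=cbz_tablet_fraction)

    def formatted(self) -> str:
        """Human-readable table: CBZ-basis values with tablet-basis in brackets."""
        lines = [f"{'Parameter':<10}" + "".join(f"{p:>16}" for p in POLYMORPHS)]
        for m in _METRICS:
            cells = [
                f"{self.table.loc[p, m]:.2f} ({self.table.loc[p, m + '_tablet']:.2f})"
                for p in POLYMORPHS
            ]
            lines.append(f"{m.upper():<10}" + "".join(f"{c:>16}" for c in cells))
        lines.append(
            f"{'R2':<10}" + "".join(f"{self.table.loc[p, 'r2']:>16.3f}" for p in POLYMORPHS)
        )
        lines.append(
            f"(n_cal={self.n_cal}, n_val={self.n_val}, "
            f"CBZ fraction of tablet={100 * self.cbz_tablet_fraction:.2f}%)"
        )
        return "\n".join(lines)


def build_report(
    design: MixtureDesign,
    cal_predictions: dict[int, np.ndarray],
    val_predictions: dict[int, np.ndarray],
    cv: CvResult | None = None,
    cv_predictions: dict[int, np.ndarray] | None = None,
) -> ErrorReport:
    """Assemble the per-polymorph error table from per-sample predictions.

    ``cal_predictions``/``val_predictions`` map sample_id to a length-3
    prediction vector (% of total CBZ mass, polymorph order CBZ I, CBZ III,
    CBZ DH).  RMSECV is taken from ``cv_predictions`` (held-out LOO
    predictions at the chosen LV count) when given, else from ``cv``.
    The tablet-basis columns use the mean CBZ tablet fraction of the
    run's design (nominally 50/300).
    """
    cal = design.calibration
    val = design.validation
    missing = [s.sample_id for s in cal if s.sample_id not in cal_predictions]
    missing += [s.sample_id for s in val if s.sample_id not in val_predictions]
    if missing:
        raise ValueError(f"predictions missing for samples {missing}")

    y_cal = cal.responses()
    y_val = val.responses()
    p_cal = np.vstack([cal_predictions[s.sample_id] for s in cal])
    p_val = np.vstack([val_predictions[s.sample_id] for s in val])
    frac = float(np.mean(design.cbz_tablet_fractions()))

    rows = {}
    for j, name in enumerate(POLYMORPHS):
        row = {
            "rmsec": rmse(y_cal[:, j], p_cal[:, j]),
            "rmsev": rmse(y_val[:, j], p_val[:, j]),
        }
        if cv_predictions is not None:
            p_cv = np.vstack([cv_predictions[s.sample_id] for s in cal])
            row["rmsecv"] = rmse(y_cal[:, j], p_cv[:, j])
        elif cv is not None and cv.chosen_n_lv is not None:
            idx = cv.lv_candidates.index(cv.chosen_n_lv)
            row["rmsecv"] = float(cv.rmsecv_per_response[idx, j])
        else:
            row["rmsecv"] = float("nan")
        for m in _METRICS:
            row[m + "_tablet"] = (
                convert_basis(row[m], frac) if np.isfinite(row[m]) else float("nan")
            )
        y_all = np.concatenate([y_cal[:, j], y_val[:, j]])
        p_all = np.concatenate([p_cal[:, j], p_val[:, j]])
        row["r2"] = r_squared(y_all, p_all)
        row["r2_cal"] = r_squared(y_cal[:, j], p_cal[:, j])
        row["r2_val"] = r_squared(y_val[:, j], p_val[:, j])
        rows[name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    return ErrorReport(table=table, n_cal=len(cal), n_val=len(val), cbz_tablet_fraction=frac)
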