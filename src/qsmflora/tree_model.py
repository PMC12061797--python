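"""Tree-level allometric flower models and predictor screening.

After upscaling, each tree contributes one flower total (the median over
QSM replicates).  The total is regressed on a single tree dimension with a
negative binomial GLM (NB2) and natural-log link:

    ln FN_t = b0 + b1 * x,    x = dbh (cm) or crown volume (m^3)

Candidate predictors are screened with Pearson correlations; pairs with
|r| > 0.7 are flagged collinear, which is why only single-predictor models
are fitted.  A row-scenario helper compares flower production of planting
schemes with fixed tree counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, CorrelationError, InsufficientDataError

#: dbh (cm) and crown-volume (m^3) calibration ranges of the reference study
CALIBRATION_RANGES = {"dbh": (9.0, 28.0), "crown_volume": (13.8, 282.7)}

CANDIDATE_PREDICTORS = [
    "dbh",
    "height",
    "crown_diameter",
    "crown_projection_area",
    "crown_volume",
]

COLLINEARITY_THRESHOLD = 0.7


@dataclass
class TreeFlowerModel:
    """NB2 regression of the tree flower total on one predictor (log link)."""

    predictor: str
    intercept: float
    slope: float
    theta: float
    se_intercept: float = float("nan")
    se_slope: float = float("nan")
    loglik: float = float("nan")
    n_trees: int = 0
    calibration_range: tuple[float, float] | None = None
    metrics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "negative binomial (NB2), log link",
            "predictor": self.predictor,
            "intercept": self.intercept,
            "slope": self.slope,
            "theta": self.theta,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "loglik": self.loglik,
            "n_trees": self.n_trees,
            "calibration_range": self.calibration_range,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def screen_predictors(
    tree_table: pd.DataFrame,
    response: str = "flowers",
    candidates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson screening of candidate predictors against the flower total.

    Returns ``(correlations, collinearity)``: per-candidate r and p-value,
    and the pairwise predictor correlations with a flag at |r| > 0.7.
    """
    if candidates is None:
        candidates = [c for c in CANDIDATE_PREDICTORS if c in tree_table.columns]
    if len(tree_table) < 3:
        raise InsufficientDataError("need at least 3 trees for screening")
    y = tree_table[response].to_numpy(float)
    rows = []
    for c in candidates:
        x = tree_table[c].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise CorrelationError(f"zero variance in {c!r} or the response")
        r, p = stats.pearsonr(x, y)
        rows.append({"predictor": c, "r": float(r), "p": float(p)})
    corr = pd.DataFrame(rows).sort_values("r", key=np.abs, ascending=False, ignore_index=True)
    pair_rows = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            r, p = stats.pearsonr(tree_table[a], tree_table[b])
            pair_rows.append(
                {
                    "a": a,
                    "b": b,
                    "r": float(r),
                    "p": float(p),
                    "collinear": bool(abs(r) > COLLINEARITY_THRESHOLD),
                }
            )
    return corr, pd.DataFrame(pair_rows)


def _nb_fit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        res = model.fit(disp=0, maxiter=500)
        for method in ("bfgs", "nm", "bfgs"):
            if res.mle_retvals.get("converged", True):
                break
            res = model.fit(disp=0, method=method, maxiter=2000, start_params=res.params)
    if not res.mle_retvals.get("converged", True):
        # accept a stalled line search if the score is essentially zero
        score = np.asarray(model.score(res.params))
        if np.max(np.abs(score)) > 1e-3 * max(1.0, abs(float(res.llf))):
            raise ConvergenceError("tree-level NB fit did not converge")
    return res


def fit_tree_model(
    tree_table: pd.DataFrame,
    predictor: str = "dbh",
    response: str = "flowers",
    loocv: bool = True,
) -> TreeFlowerModel:
    """Maximum-likelihood NB2 fit of the flower total on one predictor.

    Upscaled totals are continuous; the NB likelihood is evaluated on the
    nearest-integer totals.  The intercept is never forced through the
    origin.  In-sample MAE/RMSE/R2 and (optionally) leave-one-out CV errors
    are attached as metrics.
    """
    if len(tree_table) < 5:
        raise InsufficientDataError("need at least 5 trees to fit a tree-level model")
    x = tree_table[predictor].to_numpy(float)
    y = np.round(tree_table[response].to_numpy(float))
    if np.any(y < 0):
        raise ValueError("flower totals must be non-negative")
    X = np.column_stack([np.ones(len(x)), x])
    res = _nb_fit(y, X)
    b0, b1, alpha = res.params
    if alpha < 1e-4:
        warnings.warn(
            "dispersion at the Poisson boundary (alpha ~ 0); counts look equidispersed",
            stacklevel=2,
        )
    theta = 1.0 / alpha if alpha > 1e-12 else np.inf
    pred = np.exp(b0 + b1 * x)
    resid = y - pred
    mubar = float(np.mean(pred))
    var_f = float(np.var(b0 + b1 * x))
    var_eps = 1.0 / max(mubar, 1e-12) + (0.0 if not np.isfinite(theta) else 1.0 / theta)
    metrics = {
        "r2": var_f / (var_f + var_eps) if var_f + var_eps > 0 else 0.0,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
    if loocv:
        errs = []
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            try:
                r = _nb_fit(y[keep], X[keep])
            except Exception:
                continue
            errs.append(y[i] - np.exp(r.params[0] + r.params[1] * x[i]))
        errs = np.asarray(errs)
        metrics["mae_cv"] = float(np.mean(np.abs(errs)))
        metrics["rmse_cv"] = float(np.sqrt(np.mean(errs**2)))
    lo, hi = float(x.min()), float(x.max())
    return TreeFlowerModel(
        predictor=predictor,
        intercept=float(b0),
        slope=float(b1),
        theta=float(theta),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        loglik=float(res.llf),
        n_trees=len(x),
        calibration_range=(lo, hi),
        metrics=metrics,
    )


def predict_tree_flowers(model: TreeFlowerModel, x) -> np.ndarray | float:
    """Expected flower total exp(b0 + b1 x); warns outside calibration."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0):
        raise ValueError("predictor value must be > 0")
    rng = model.calibration_range or CALIBRATION_RANGES.get(model.predictor)
    if rng is not None and (np.any(x_arr < rng[0]) or np.any(x_arr > rng[1])):
        warnings.warn(
            f"{model.predictor} outside the calibration range {rng}; extrapolating",
            stacklevel=2,
        )
    out = np.exp(model.intercept + model.slope * x_arr)
    return out if out.shape else float(out)


def fold_increase(percent: float, rate_per_percent: float) -> float:
    """Multiplicative flower increase for a dbh increase of ``percent`` %
    at the model's baseline: exp(rate * percent)."""
    return float(np.exp(rate_per_percent * percent))


def row_flower_total(n_trees: int, flowers_per_tree: float) -> float:
    """Total flowers of a planting row with ``n_trees`` identical trees."""
    if n_trees < 0:
        raise ValueError("tree count must be >= 0")
    return float(n_trees) * float(flowers_per_tree)


def row_ratio(
    n_trees_a: int, flowers_a: float, n_trees_b: int, flowers_b: float
) -> float:
    """Flower-production ratio of row scenario A over scenario B."""
    denom = row_flower_total(n_trees_b, flowers_b)
    if denom == 0:
        raise ZeroDivisionError("scenario B produces no flowers")
    return row_flower_total(n_trees_a, flowers_a) / denom
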