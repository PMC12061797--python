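"""Two-part hurdle model of flower occurrence and abundance on branches.

The branch-level flower count is modelled in two parts:

* **occurrence** — a binomial regression with logit link for whether a
  branch carries any flowers:
  ``logit p = b0 + b1 ln D + b2 dbh + layer + stratum + layer:stratum``
* **abundance** — a zero-truncated negative binomial (ZTNB, NB2) regression
  for the count given at least one flower:
  ``ln mu = b0 + b1 ln D + b2 dbh + layer + stratum + b5 ln D * dbh
  + layer:stratum``

where D is the branch cut-off diameter in mm, dbh the stem diameter in cm,
crown layer in {in, out} (reference: out) and crown stratum in
{bot, mid, top} (reference: bot).  The abundance linear predictor is the log
mean of the *untruncated* NB; the reported conditional expectation is the
zero-truncated mean ``mu / (1 - (theta/(theta+mu))^theta)``.

A nested random intercept (cut-off branch within tree) can be estimated by
a Laplace approximation; the fixed-effects-only fit is the deterministic
default and is exact when the random SDs are zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP

from .errors import (
    ConvergenceError,
    DegenerateFitError,
    InsufficientDataError,
    NestingError,
    SpecificationError,
)

Part = Literal["occurrence", "abundance"]

_FIELDS = (
    "intercept",
    "ln_diameter",
    "dbh",
    "layer_in",
    "stratum_mid",
    "stratum_top",
    "in_mid",
    "in_top",
    "ln_diameter_dbh",
)


@dataclass(frozen=True)
class PartCoefficients:
    """Fixed-effect coefficients of one hurdle part.

    Reference levels are layer = out and stratum = bot.
    ``ln_diameter_dbh`` is the ln(D) x dbh interaction of the abundance
    part; it is ``None`` for the occurrence part.
    """

    intercept: float
    ln_diameter: float
    dbh: float
    layer_in: float
    stratum_mid: float
    stratum_top: float
    in_mid: float
    in_top: float
    ln_diameter_dbh: float | None = None

    def names(self) -> list[str]:
        return [f for f in _FIELDS if getattr(self, f) is not None]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.names()], dtype=float)

    @classmethod
    def from_mapping(cls, values: dict[str, float]) -> "PartCoefficients":
        return cls(**{f: values.get(f) for f in _FIELDS})


@dataclass(frozen=True)
class HurdleCoefficients:
    """Full hurdle parameter set: both parts, ZTNB dispersion theta and
    the random-intercept SDs (tree, and cut-off branch within tree)."""

    occurrence: PartCoefficients
    abundance: PartCoefficients
    theta: float = 1.5
    sd_tree: float = 0.0
    sd_branch: float = 0.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sd_tree < 0 or self.sd_branch < 0:
            raise ValueError("random-intercept SDs must be >= 0")


# ---------------------------------------------------------------------------
# linear predictors and predictions


def _as_arrays(*vals):
    arrs = np.broadcast_arrays(*[np.asarray(v) for v in vals])
    return arrs


def linear_predictor(
    part: PartCoefficients,
    diameter_mm,
    dbh_cm,
    layer,
    stratum,
    random_intercept=0.0,
):
    """Evaluate the linear predictor (link scale) for one hurdle part."""
    D, dbh, lay, st, ri = _as_arrays(diameter_mm, dbh_cm, layer, stratum, random_intercept)
    if np.any(D.astype(float) <= 0) or np.any(dbh.astype(float) <= 0):
        raise ValueError("diameter and dbh must be > 0")
    lnD = np.log(D.astype(float))
    is_in = (lay == "in").astype(float)
    is_mid = (st == "mid").astype(float)
    is_top = (st == "top").astype(float)
    eta = (
        part.intercept
        + part.ln_diameter * lnD
        + part.dbh * dbh.astype(float)
        + part.layer_in * is_in
        + part.stratum_mid * is_mid
        + part.stratum_top * is_top
        + part.in_mid * is_in * is_mid
        + part.in_top * is_in * is_top
        + ri.astype(float)
    )
    if part.ln_diameter_dbh is not None:
        eta = eta + part.ln_diameter_dbh * lnD * dbh.astype(float)
    return eta if eta.shape else float(eta)


def predict_occurrence_probability(
    diameter_mm, dbh_cm, layer, stratum, coefs: HurdleCoefficients, random_intercept=0.0
):
    """Probability that a branch carries at least one flower."""
    eta = linear_predictor(
        coefs.occurrence, diameter_mm, dbh_cm, layer, stratum, random_intercept
    )
    return special.expit(eta)


def ztnb_mean(mu, theta: float):
    """Mean of the zero-truncated NB2 with untruncated mean mu."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    mu = np.asarray(mu, dtype=float)
    # (theta/(theta+mu))^theta computed in log space for stability
    log_p0 = -theta * np.log1p(mu / theta)
    denom = -np.expm1(log_p0)
    out = np.where(mu > 0, mu / np.where(denom > 0, denom, 1.0), 1.0)
    # mu -> 0 limit of the truncated mean is 1
    small = mu < 1e-10
    if np.any(small):
        out = np.where(small, 1.0, out)
    return out if out.shape else float(out)


def predict_conditional_count(
    diameter_mm, dbh_cm, layer, stratum, coefs: HurdleCoefficients, random_intercept=0.0
):
    """Expected flower count on a branch given that it carries flowers."""
    eta = linear_predictor(
        coefs.abundance, diameter_mm, dbh_cm, layer, stratum, random_intercept
    )
    return ztnb_mean(np.exp(eta), coefs.theta)


def predict_unconditional_count(
    diameter_mm, dbh_cm, layer, stratum, coefs: HurdleCoefficients
):
    """p * E[N | N >= 1]: the combined hurdle expectation."""
    p = predict_occurrence_probability(diameter_mm, dbh_cm, layer, stratum, coefs)
    m = predict_conditional_count(diameter_mm, dbh_cm, layer, stratum, coefs)
    return p * m


# ---------------------------------------------------------------------------
# design matrices

OCC_COLUMNS = list(_FIELDS[:-1])
AB_COLUMNS = list(_FIELDS)


def design_matrix(df: pd.DataFrame, part: Part) -> tuple[np.ndarray, list[str]]:
    """Model matrix from a branch table with columns
    ``cutoff_diameter_mm, dbh_cm, layer, stratum``."""
    lnD = np.log(df["cutoff_diameter_mm"].to_numpy(dtype=float))
    dbh = df["dbh_cm"].to_numpy(dtype=float)
    is_in = (df["layer"] == "in").to_numpy(dtype=float)
    is_mid = (df["stratum"] == "mid").to_numpy(dtype=float)
    is_top = (df["stratum"] == "top").to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(df)),
        "ln_diameter": lnD,
        "dbh": dbh,
        "layer_in": is_in,
        "stratum_mid": is_mid,
        "stratum_top": is_top,
        "in_mid": is_in * is_mid,
        "in_top": is_in * is_top,
    }
    names = list(OCC_COLUMNS)
    if part == "abundance":
        cols["ln_diameter_dbh"] = lnD * dbh
        names = list(AB_COLUMNS)
    X = np.column_stack([cols[c] for c in names])
    return X, names


# ---------------------------------------------------------------------------
# per-observation log-likelihoods (used by the Laplace layer)


def _bernoulli_nll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta) - y * eta


def ztnb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """Log pmf of the zero-truncated NB2 at counts y >= 1."""
    log_nb = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        - theta * np.log1p(mu / theta)
        + y * (np.log(mu) - np.log(theta + mu))
    )
    log_p0 = -theta * np.log1p(mu / theta)
    return log_nb - np.log(-np.expm1(log_p0))


def _ztnb_nll(eta: np.ndarray, y: np.ndarray, theta: float) -> np.ndarray:
    return -ztnb_logpmf(y, np.exp(eta), theta)


# ---------------------------------------------------------------------------
# fit results


@dataclass
class PartFit:
    """Fit of a single hurdle part."""

    part: Part
    param_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray | None
    loglik: float
    n_obs: int
    theta: float | None = None
    theta_se: float | None = None
    sd_tree: float = 0.0
    sd_branch: float = 0.0
    covariate_means: dict[str, float] = field(default_factory=dict)
    conditional_modes: dict[tuple[str, str], float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_params(self) -> int:
        extra = 0 if self.theta is None else 1
        extra += int(self.sd_tree > 0) + int(self.sd_branch > 0)
        return len(self.params) + extra

    def coefficients(self) -> PartCoefficients:
        return PartCoefficients.from_mapping(dict(zip(self.param_names, self.params)))


@dataclass
class HurdleFit:
    """Joint result of the two part-fits."""

    occurrence: PartFit
    abundance: PartFit

    @property
    def loglik(self) -> float:
        return self.occurrence.loglik + self.abundance.loglik

    def coefficients(self) -> HurdleCoefficients:
        return HurdleCoefficients(
            occurrence=self.occurrence.coefficients(),
            abundance=self.abundance.coefficients(),
            theta=self.abundance.theta if self.abundance.theta else 1.5,
            sd_tree=max(self.occurrence.sd_tree, self.abundance.sd_tree),
            sd_branch=max(self.occurrence.sd_branch, self.abundance.sd_branch),
        )

    def to_json(self, path: str | Path) -> None:
        def pack(p: PartFit) -> dict:
            return {
                "part": p.part,
                "param_names": p.param_names,
                "params": list(map(float, p.params)),
                "bse": list(map(float, p.bse)),
                "loglik": float(p.loglik),
                "n_obs": p.n_obs,
                "theta": p.theta,
                "theta_se": p.theta_se,
                "sd_tree": p.sd_tree,
                "sd_branch": p.sd_branch,
                "covariate_means": p.covariate_means,
            }

        payload = {
            "model": "hurdle(binomial-logit, zero-truncated NB2)",
            "abundance_link_convention": "linear predictor is ln(mu) of the untruncated NB",
            "occurrence": pack(self.occurrence),
            "abundance": pack(self.abundance),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _prepare_frame(
    records_or_df, trees=None
) -> pd.DataFrame:
    """Accept a prepared DataFrame or (records, trees) and return the
    modelling frame with dbh merged in."""
    if isinstance(records_or_df, pd.DataFrame):
        df = records_or_df.copy()
    else:
        from .branch_data import records_to_frame, trees_to_frame

        df = records_to_frame(records_or_df)
    if "dbh_cm" not in df.columns:
        if trees is None:
            raise SpecificationError("need tree records (dbh) to build the model frame")
        from .branch_data import trees_to_frame

        tdf = trees if isinstance(trees, pd.DataFrame) else trees_to_frame(trees)
        df = df.merge(tdf[["tree_id", "dbh_cm"]], on="tree_id", how="left")
    if df["dbh_cm"].isna().any():
        raise SpecificationError("some branches have no matching tree dbh")
    return df


def fit_hurdle(
    records_or_df,
    trees=None,
    random_effects: bool = False,
    group_col: str = "branch_id",
    tree_col: str = "tree_id",
    compute_se: bool = True,
) -> HurdleFit:
    """Fit both hurdle parts by maximum likelihood.

    With ``random_effects=False`` (the deterministic default) ordinary
    logistic and zero-truncated NB regressions are fitted; with
    ``random_effects=True`` a nested random intercept (``group_col`` within
    ``tree_col``) is integrated out by a Laplace approximation.
    """
    df = _prepare_frame(records_or_df, trees)
    y = df["flowers"].to_numpy(dtype=float)
    y01 = (y > 0).astype(float)
    if y01.min() == y01.max():
        raise DegenerateFitError(
            "need both zero and nonzero flower counts to fit a hurdle model"
        )
    if df[tree_col].nunique() < 2 and not random_effects:
        warnings.warn("only one tree in the data; dbh effect is unidentifiable", stacklevel=2)

    if random_effects:
        occ = _fit_part_laplace(df, "occurrence", group_col, tree_col, compute_se)
        ab = _fit_part_laplace(df, "abundance", group_col, tree_col, compute_se)
    else:
        occ = _fit_occurrence_fixed(df, y01)
        ab = _fit_abundance_fixed(df, y)
    return HurdleFit(occurrence=occ, abundance=ab)


def _covariate_means(df: pd.DataFrame) -> dict[str, float]:
    return {
        "ln_diameter": float(np.log(df["cutoff_diameter_mm"]).mean()),
        "dbh": float(df["dbh_cm"].mean()),
    }


def _fit_occurrence_fixed(df: pd.DataFrame, y01: np.ndarray) -> PartFit:
    X, names = design_matrix(df, "occurrence")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y01, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    if not res.mle_retvals.get("converged", True):
        res = model.fit(disp=0, method="bfgs", maxiter=1000, start_params=res.params)
    try:
        cov = np.asarray(res.cov_params())
        bse = np.asarray(res.bse)
    except Exception:  # singular design (e.g. constant covariates)
        cov = np.linalg.pinv(-np.asarray(model.hessian(np.asarray(res.params))))
        bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return PartFit(
        part="occurrence",
        param_names=names,
        params=np.asarray(res.params),
        bse=bse,
        cov=cov,
        loglik=float(res.llf),
        n_obs=len(df),
        covariate_means=_covariate_means(df),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def _fit_abundance_fixed(df: pd.DataFrame, y: np.ndarray) -> PartFit:
    pos = y > 0
    sub = df.loc[pos]
    X, names = design_matrix(sub, "abundance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = TruncatedLFNegativeBinomialP(y[pos], X, truncation=0)
        # moment-based start: OLS on log counts, moderate overdispersion
        start = np.append(np.linalg.lstsq(X, np.log(y[pos]), rcond=None)[0], 0.7)
        res = model.fit(disp=0, method="bfgs", maxiter=500, start_params=start)
        last = "bfgs"
        for method in ("nm", "bfgs", "nm", "bfgs"):
            if res.mle_retvals.get("converged", True) and np.isfinite(res.llf):
                break
            prev = res.params if np.isfinite(res.llf) else start
            res = model.fit(disp=0, method=method, maxiter=5000, start_params=prev)
            last = method
        if last == "nm":  # simplex carries no Hessian; polish for covariances
            res = model.fit(disp=0, method="bfgs", maxiter=200, start_params=res.params)
    if not res.mle_retvals.get("converged", True):
        score = np.asarray(model.score(res.params))
        if np.max(np.abs(score)) > 1e-3 * max(1.0, abs(float(res.llf))):
            raise ConvergenceError("zero-truncated NB part did not converge")
    params = np.asarray(res.params)
    try:
        cov_all = np.asarray(res.cov_params())
        bse = np.asarray(res.bse)
    except ValueError:  # optimizer returned no covariance; use the Hessian
        H = np.asarray(model.hessian(params))
        if np.isfinite(H).all():
            cov_all = np.linalg.pinv(-H)
        else:
            cov_all = np.full((len(params), len(params)), np.nan)
        bse = np.sqrt(np.maximum(np.diag(cov_all), 0.0))
    alpha = params[-1]  # NB2 alpha = 1/theta
    theta = 1.0 / alpha if alpha > 0 else np.inf
    theta_se = bse[-1] / alpha**2 if alpha > 0 and np.isfinite(bse[-1]) else None
    return PartFit(
        part="abundance",
        param_names=names,
        params=params[:-1],
        bse=bse[:-1],
        cov=cov_all[:-1, :-1],
        loglik=float(res.llf),
        n_obs=int(pos.sum()),
        theta=float(theta),
        theta_se=None if theta_se is None else float(theta_se),
        covariate_means=_covariate_means(sub),
    )


# ---------------------------------------------------------------------------
# Laplace-approximated nested random intercepts

_SD_FLOOR = 1e-4


def _numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, eps: float = 1e-4):
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(d):
        ei = np.zeros(d); ei[i] = steps[i]
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _bernoulli_d1d2(eta, y, _theta=None):
    """First and second derivatives of the Bernoulli nll w.r.t. eta."""
    p = special.expit(eta)
    return p - y, np.maximum(p * (1.0 - p), 1e-10)


def _ztnb_d1d2(eta, y, theta):
    """Derivatives of the ZTNB nll w.r.t. eta (second one numeric)."""

    def d1(e):
        mu = np.exp(e)
        log_p0 = -theta * np.log1p(mu / theta)
        p0 = np.exp(log_p0)
        grad_ll = theta * (y - mu) / (theta + mu) - p0 * theta * mu / (
            (theta + mu) * np.maximum(1.0 - p0, 1e-12)
        )
        return -grad_ll

    h = 1e-5
    d2 = (d1(eta + h) - d1(eta - h)) / (2 * h)
    return d1(eta), np.maximum(d2, 1e-10)


def _block_laplace(
    eta_fixed: np.ndarray,
    y: np.ndarray,
    branch_codes: np.ndarray,
    nll_fn: Callable,
    d1d2_fn: Callable,
    sd_tree: float,
    sd_branch: float,
    theta: float | None = None,
):
    """Laplace-approximate one tree block's marginal log-likelihood.

    The random-effect vector is [v_1..v_k, u] (branch deviations then the
    tree deviation); the penalized-nll Hessian is an arrow matrix (diagonal
    in v with a dense border for u), so the Newton step and the log-
    determinant are computed in O(k).  Returns (loglik, u, v).
    """
    n_branch = int(branch_codes.max()) + 1 if len(branch_codes) else 0
    use_tree = sd_tree > _SD_FLOOR
    use_branch = sd_branch > _SD_FLOOR

    def nll_sum(u, v):
        eta = eta_fixed + u + (v[branch_codes] if use_branch else 0.0)
        val = float(np.sum(nll_fn(eta, y, theta)))
        if use_tree:
            val += 0.5 * (u / sd_tree) ** 2 + 0.5 * np.log(2 * np.pi * sd_tree**2)
        if use_branch:
            val += 0.5 * float(np.sum((v / sd_branch) ** 2)) + n_branch * 0.5 * np.log(
                2 * np.pi * sd_branch**2
            )
        return val

    u = 0.0
    v = np.zeros(n_branch)
    dims = int(use_tree) + (n_branch if use_branch else 0)
    if dims == 0:
        return -nll_sum(0.0, v), 0.0, v

    f_cur = nll_sum(u, v)
    for _ in range(50):
        eta = eta_fixed + u + (v[branch_codes] if use_branch else 0.0)
        d1, d2 = d1d2_fn(eta, y, theta)
        # per-branch sums of the observation weights
        s1 = np.bincount(branch_codes, weights=d1, minlength=n_branch)
        s2 = np.bincount(branch_codes, weights=d2, minlength=n_branch)
        g_v = s1 + v / sd_branch**2 if use_branch else np.zeros(0)
        g_u = float(np.sum(d1)) + (u / sd_tree**2 if use_tree else 0.0)
        d_v = s2 + 1.0 / sd_branch**2  # diagonal (branch) entries
        a = float(np.sum(d2)) + (1.0 / sd_tree**2 if use_tree else 0.0)
        # Newton direction for the arrow system
        if use_branch and use_tree:
            inv_gv = g_v / d_v
            schur = a - float(np.sum(s2**2 / d_v))
            du = -(g_u - float(np.sum(s2 * inv_gv))) / max(schur, 1e-10)
            dv = -(g_v + s2 * du) / d_v
        elif use_branch:
            du = 0.0
            dv = -g_v / d_v
        else:
            du = -g_u / a
            dv = np.zeros(0)
        # damped step
        step = 1.0
        for _ls in range(30):
            u_new = u + step * du
            v_new = v + step * dv if use_branch else v
            f_new = nll_sum(u_new, v_new)
            if f_new <= f_cur + 1e-12:
                break
            step *= 0.5
        moved = abs(f_cur - f_new)
        u, v, f_cur = u_new, v_new, f_new
        if moved < 1e-10:
            break

    # log-determinant of the arrow Hessian at the mode
    eta = eta_fixed + u + (v[branch_codes] if use_branch else 0.0)
    _, d2 = d1d2_fn(eta, y, theta)
    s2 = np.bincount(branch_codes, weights=d2, minlength=n_branch)
    if use_branch:
        d_v = s2 + 1.0 / sd_branch**2
        logdet = float(np.sum(np.log(d_v)))
        if use_tree:
            a = float(np.sum(d2)) + 1.0 / sd_tree**2
            logdet += np.log(max(a - float(np.sum(s2**2 / d_v)), 1e-10))
    else:
        a = float(np.sum(d2)) + 1.0 / sd_tree**2
        logdet = float(np.log(max(a, 1e-10)))
    ll = -f_cur + 0.5 * dims * np.log(2 * np.pi) - 0.5 * logdet
    return float(ll), float(u), v


def _fit_part_laplace(
    df: pd.DataFrame, part: Part, group_col: str, tree_col: str, compute_se: bool
) -> PartFit:
    y_all = df["flowers"].to_numpy(dtype=float)
    if part == "occurrence":
        sub = df
        y = (y_all > 0).astype(float)
    else:
        sub = df.loc[y_all > 0]
        y = y_all[y_all > 0]
    X, names = design_matrix(sub, part)
    k = X.shape[1]
    trees = sub[tree_col].to_numpy()
    groups = sub[group_col].to_numpy()
    tree_ids = pd.unique(trees)
    blocks = []
    for t in tree_ids:
        m = trees == t
        codes, _ = pd.factorize(groups[m])
        blocks.append((np.where(m)[0], codes))
    n_trees = len(tree_ids)
    single_tree = n_trees < 2
    if single_tree:
        warnings.warn(
            "single tree: tree-level random SD fixed at the boundary (0)", stacklevel=3
        )

    # start from the fixed-effects fit
    fixed = (
        _fit_occurrence_fixed(sub.assign(flowers=y), y)
        if part == "occurrence"
        else _fit_abundance_fixed(sub.assign(flowers=y), y)
    )
    theta0 = fixed.theta if part == "abundance" else None

    # upper bound guards the flat-likelihood drift of binary data with
    # small groups (separable groups make the Laplace profile asymptote)
    log_sd_bounds = (np.log(_SD_FLOOR / 2), np.log(5.0))

    if part == "abundance":
        nll_fn = lambda eta, yy, th: _ztnb_nll(eta, yy, th)
        d1d2_fn = _ztnb_d1d2
    else:
        nll_fn = lambda eta, yy, th: _bernoulli_nll(eta, yy)
        d1d2_fn = _bernoulli_d1d2

    def nll_outer(params):
        beta = params[:k]
        log_sd_t = params[k] if not single_tree else log_sd_bounds[0]
        log_sd_b = params[k + (0 if single_tree else 1)]
        sd_t = float(np.exp(log_sd_t))
        sd_b = float(np.exp(log_sd_b))
        theta = float(np.exp(params[-1])) if part == "abundance" else None
        eta_fixed = X @ beta
        total = 0.0
        for idx, codes in blocks:
            ll, _, _ = _block_laplace(
                eta_fixed[idx], y[idx], codes, nll_fn, d1d2_fn, sd_t, sd_b, theta
            )
            total -= ll
        return total

    x0 = list(fixed.params) + ([] if single_tree else [np.log(0.3)]) + [np.log(0.3)]
    if part == "abundance":
        x0.append(np.log(theta0 if theta0 and np.isfinite(theta0) else 1.5))
    x0 = np.array(x0, dtype=float)
    bounds = [(None, None)] * k
    bounds += [] if single_tree else [log_sd_bounds]
    bounds += [log_sd_bounds]
    if part == "abundance":
        bounds += [(np.log(1e-2), np.log(1e3))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            nll_outer, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 300}
        )
    params = res.x
    beta = params[:k]
    sd_t = 0.0 if single_tree else float(np.exp(params[k]))
    sd_b = float(np.exp(params[k + (0 if single_tree else 1)]))
    if sd_t <= _SD_FLOOR:
        sd_t = 0.0
    if sd_b <= _SD_FLOOR:
        sd_b = 0.0
    upper = np.exp(log_sd_bounds[1]) * 0.99
    if sd_t > upper or sd_b > upper:
        warnings.warn(
            f"{part}: random-intercept SD at the upper bound; the variance is "
            "weakly identified (typical for binary data with small groups)",
            stacklevel=3,
        )
    theta = float(np.exp(params[-1])) if part == "abundance" else None

    # conditional modes at the optimum
    eta_fixed = X @ beta
    modes: dict[tuple[str, str], float] = {}
    for (idx, codes), t in zip(blocks, tree_ids):
        _, u, v = _block_laplace(
            eta_fixed[idx], y[idx], codes, nll_fn, d1d2_fn, sd_t, sd_b, theta
        )
        for local, g in enumerate(pd.unique(groups[idx])):
            vb = v[local] if len(v) > local else 0.0
            modes[(str(t), str(g))] = float(u + vb)

    bse = np.full(k, np.nan)
    cov = None
    if compute_se:
        H = _numeric_hessian(nll_outer, params, eps=1e-4)
        try:
            cov_full = np.linalg.inv(H)
            cov = cov_full[:k, :k]
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass
    return PartFit(
        part=part,
        param_names=names,
        params=beta,
        bse=bse,
        cov=cov,
        loglik=-float(res.fun),
        n_obs=len(y),
        theta=theta,
        sd_tree=sd_t,
        sd_branch=sd_b,
        covariate_means=_covariate_means(sub),
        conditional_modes=modes,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(model_full: PartFit, model_reduced: PartFit) -> LRTResult:
    """Chi-square LRT of a reduced against a full (nested) part-fit."""
    if not set(model_reduced.param_names) <= set(model_full.param_names):
        raise NestingError("reduced model terms are not a subset of the full model's")
    df = model_full.n_params - model_reduced.n_params
    if df < 0:
        raise NestingError("reduced model has more parameters than the full model")
    stat = max(0.0, 2.0 * (model_full.loglik - model_reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, pvalue=p)


def _fit_part_columns(df: pd.DataFrame, part: Part, keep: list[str]) -> PartFit:
    """Refit one part on a column subset of the full design matrix."""
    y = df["flowers"].to_numpy(dtype=float)
    if part == "occurrence":
        fit = _fit_occurrence_fixed(df, (y > 0).astype(float))
    else:
        fit = _fit_abundance_fixed(df, y)
    if set(keep) == set(fit.param_names):
        return fit
    X, names = design_matrix(df.loc[y > 0] if part == "abundance" else df, part)
    idx = [i for i, n in enumerate(names) if n in keep]
    Xr = X[:, idx]
    kept = [names[i] for i in idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if part == "occurrence":
            res = sm.Logit((y > 0).astype(float), Xr).fit(disp=0, method="bfgs", maxiter=500)
            theta = None
            params, bse, ll = np.asarray(res.params), np.asarray(res.bse), float(res.llf)
        else:
            yp = y[y > 0]
            model = TruncatedLFNegativeBinomialP(yp, Xr, truncation=0)
            start = np.append(np.linalg.lstsq(Xr, np.log(yp), rcond=None)[0], 0.7)
            res = model.fit(disp=0, method="bfgs", maxiter=500, start_params=start)
            p = np.asarray(res.params)
            theta = 1.0 / p[-1] if p[-1] > 0 else np.inf
            params, bse, ll = p[:-1], np.asarray(res.bse)[:-1], float(res.llf)
    return PartFit(
        part=part, param_names=kept, params=params, bse=bse, cov=None,
        loglik=ll, n_obs=fit.n_obs, theta=theta,
        covariate_means=fit.covariate_means,
    )


#: term groups the stepwise reduction may drop, in marginality-safe order
_DROPPABLE = {
    "occurrence": [["in_mid", "in_top"], ["stratum_mid", "stratum_top"], ["layer_in"], ["dbh"]],
    "abundance": [
        ["in_mid", "in_top"],
        ["ln_diameter_dbh"],
        ["stratum_mid", "stratum_top"],
        ["layer_in"],
        ["dbh"],
    ],
}


def backward_select(
    records_or_df, trees=None, part: Part = "occurrence", alpha: float = 0.05
) -> tuple[PartFit, list[str]]:
    """Stepwise reduction of one hurdle part by likelihood-ratio tests.

    Starting from the full fixed-effects model, term groups are dropped
    (interactions before their main effects) whenever the LRT against the
    current model is non-significant at ``alpha`` — if a reduction does not
    hurt, the simpler model wins.  Returns the selected fit and a log of
    the dropped groups.
    """
    df = _prepare_frame(records_or_df, trees)
    keep = list(AB_COLUMNS if part == "abundance" else OCC_COLUMNS)
    current = _fit_part_columns(df, part, keep)
    dropped: list[str] = []
    changed = True
    while changed:
        changed = False
        for group in _DROPPABLE[part]:
            if not set(group) <= set(keep):
                continue
            # marginality: keep main effects while their interaction is in
            if group == ["layer_in"] and {"in_mid", "in_top"} & set(keep):
                continue
            if group == ["stratum_mid", "stratum_top"] and {"in_mid", "in_top"} & set(keep):
                continue
            if group == ["dbh"] and "ln_diameter_dbh" in keep:
                continue
            reduced = _fit_part_columns(df, part, [c for c in keep if c not in group])
            if likelihood_ratio_test(current, reduced).pvalue >= alpha:
                keep = [c for c in keep if c not in group]
                current = reduced
                dropped.append("+".join(group))
                changed = True
                break
    return current, dropped


# ---------------------------------------------------------------------------
# estimated marginal means with Tukey-adjusted pairwise comparisons

_LEVELS = {"layer": ("in", "out"), "stratum": ("bot", "mid", "top")}


def _grid_row(part: Part, layer: str, stratum: str, means: dict[str, float]) -> np.ndarray:
    lnD = means["ln_diameter"]
    dbh = means["dbh"]
    is_in = 1.0 if layer == "in" else 0.0
    is_mid = 1.0 if stratum == "mid" else 0.0
    is_top = 1.0 if stratum == "top" else 0.0
    row = [1.0, lnD, dbh, is_in, is_mid, is_top, is_in * is_mid, is_in * is_top]
    if part == "abundance":
        row.append(lnD * dbh)  # ln_diameter_dbh is the last design column
    return np.array(row)


def estimated_marginal_means(
    fit: PartFit, factor: Literal["layer", "stratum"]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal means on the link scale over a balanced reference grid.

    For each level of ``factor`` the linear predictor is averaged over all
    levels of the other crown factor, with ln(D) and dbh held at their
    training means.  Returns ``(means, comparisons)`` where comparisons hold
    Tukey-adjusted (studentized-range) pairwise p-values.
    """
    if factor not in _LEVELS:
        raise SpecificationError(f"unknown factor {factor!r}")
    needed = {"layer_in", "stratum_mid", "stratum_top"}
    if not needed <= set(fit.param_names):
        raise SpecificationError("crown factors are absent from the fitted model")
    if fit.cov is None:
        raise SpecificationError("fit carries no coefficient covariance matrix")
    other = "stratum" if factor == "layer" else "layer"
    means = fit.covariate_means
    L = {}
    for lev in _LEVELS[factor]:
        rows = []
        for o in _LEVELS[other]:
            layer, stratum = (lev, o) if factor == "layer" else (o, lev)
            rows.append(_grid_row(fit.part, layer, stratum, means))
        L[lev] = np.mean(rows, axis=0)
    # column order of _grid_row matches design_matrix order
    est = {lev: float(v @ fit.params) for lev, v in L.items()}
    se = {lev: float(np.sqrt(v @ fit.cov @ v)) for lev, v in L.items()}
    mean_df = pd.DataFrame(
        {"level": list(est), "emmean": list(est.values()), "se": list(se.values())}
    )
    levels = list(_LEVELS[factor])
    k = len(levels)
    comp_rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            d = L[a] - L[b]
            diff = float(d @ fit.params)
            sed = float(np.sqrt(d @ fit.cov @ d))
            if sed == 0:
                p = 1.0
            else:
                q = abs(diff) / sed * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, 1e7))
            comp_rows.append(
                {"contrast": f"{a} - {b}", "estimate": diff, "se": sed, "p_tukey": p}
            )
    return mean_df, pd.DataFrame(comp_rows)


# ---------------------------------------------------------------------------
# fit metrics

_PI2_3 = np.pi**2 / 3  # kept for reference; the delta-method variant is used


@dataclass(frozen=True)
class FitMetrics:
    r2_marginal: float
    r2_conditional: float
    mae_marginal: float
    mae_conditional: float
    rmse_marginal: float
    rmse_conditional: float
    mae_cv: float | None = None
    rmse_cv: float | None = None
    r2_variant: str = "nakagawa-delta"


def _part_response(fit: PartFit, df: pd.DataFrame, random_offsets: np.ndarray):
    """(observed, predicted) on the response scale for one part."""
    X, _ = design_matrix(df, fit.part)
    eta = X @ fit.params + random_offsets
    y = df["flowers"].to_numpy(dtype=float)
    if fit.part == "occurrence":
        return (y > 0).astype(float), special.expit(eta)
    return y, ztnb_mean(np.exp(eta), fit.theta)


def _offsets_for(fit: PartFit, df: pd.DataFrame, group_col: str, tree_col: str):
    if not fit.conditional_modes:
        return np.zeros(len(df))
    keys = list(zip(df[tree_col].astype(str), df[group_col].astype(str)))
    return np.array([fit.conditional_modes.get(k, 0.0) for k in keys])


def fit_metrics(
    fit: PartFit,
    records_or_df,
    trees=None,
    loocv: bool = False,
    group_col: str = "branch_id",
    tree_col: str = "tree_id",
) -> FitMetrics:
    """Marginal/conditional R2 (Nakagawa, delta-method residual variance),
    MAE and RMSE, plus leave-one-group-out CV errors on request.

    Marginal quantities use fixed effects only; conditional quantities add
    the predicted (conditional-mode) random intercepts.  The LOOCV unit is
    the random-effect group (the cut-off branch), predicted marginally.
    """
    df = _prepare_frame(records_or_df, trees)
    if fit.part == "abundance":
        df = df.loc[df["flowers"] > 0]
    X, _ = design_matrix(df, fit.part)
    zero = np.zeros(len(df))
    y, pred_m = _part_response(fit, df, zero)
    offs = _offsets_for(fit, df, group_col, tree_col)
    _, pred_c = _part_response(fit, df, offs)

    eta_fixed = X @ fit.params
    var_f = float(np.var(eta_fixed))
    var_r = fit.sd_tree**2 + fit.sd_branch**2
    if fit.part == "occurrence":
        pbar = float(np.mean(special.expit(eta_fixed)))
        var_eps = 1.0 / max(pbar * (1 - pbar), 1e-12)
    else:
        mubar = float(np.mean(np.exp(eta_fixed)))
        inv_theta = 0.0 if (fit.theta is None or not np.isfinite(fit.theta)) else 1.0 / fit.theta
        var_eps = 1.0 / max(mubar, 1e-12) + inv_theta
    denom = var_f + var_r + var_eps
    r2m = min(1.0, var_f / denom) if denom > 0 else 0.0
    r2c = min(1.0, (var_f + var_r) / denom) if denom > 0 else 0.0

    def mae(a, b):
        return float(np.mean(np.abs(a - b)))

    def rmse(a, b):
        return float(np.sqrt(np.mean((a - b) ** 2)))

    mae_cv = rmse_cv = None
    if loocv:
        groups = df[group_col].unique()
        if len(groups) < 3:
            raise InsufficientDataError("LOOCV needs at least 3 groups")
        errs = []
        for g in groups:
            train = df.loc[df[group_col] != g]
            test = df.loc[df[group_col] == g]
            try:
                if fit.part == "occurrence":
                    sub = _fit_occurrence_fixed(train, (train["flowers"] > 0).to_numpy(float))
                else:
                    sub = _fit_abundance_fixed(train, train["flowers"].to_numpy(float))
            except Exception:
                continue
            yt, pt = _part_response(sub, test, np.zeros(len(test)))
            errs.extend(yt - pt)
        errs = np.asarray(errs)
        mae_cv = float(np.mean(np.abs(errs)))
        rmse_cv = float(np.sqrt(np.mean(errs**2)))

    return FitMetrics(
        r2_marginal=r2m,
        r2_conditional=r2c,
        mae_marginal=mae(y, pred_m),
        mae_conditional=mae(y, pred_c),
        rmse_marginal=rmse(y, pred_m),
        rmse_conditional=rmse(y, pred_c),
        mae_cv=mae_cv,
        rmse_cv=rmse_cv,
    )
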