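"""Missing-data strategies for responder analysis.

Three strategies are implemented:

* ``NRI`` — non-response imputation: every subject whose responder status
  cannot be determined is counted as a non-responder (single imputation).
* ``IBD`` — impute before dichotomizing: the continuous outcomes are
  multiply imputed by fully conditional specification (FCS), then responder
  status is computed on each completed dataset.
* ``DTI`` — dichotomize then impute: responder status is computed first and
  the partially observed binary indicator is imputed directly, alongside the
  continuous outcomes, using a logistic conditional model.

The FCS engine cycles through the partially observed variables in a fixed
order, refitting each conditional model on the currently completed data and
redrawing that variable's missing entries from a proper posterior draw:
normal-inverse-chi-squared for linear conditionals, asymptotic-normal
coefficient draws for logistic conditionals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .pooling import ArmProportionEstimate, diff_proportions
from .trial import DEFAULT_RULE, N_VISITS, ResponderRule, TrialDataset, classify_responders

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGIES",
    "VariableSpec",
    "ImputationModelSpec",
    "ImputationResult",
    "nri_impute",
    "fill_in_start",
    "impute_continuous_draw",
    "impute_binary_draw",
    "fcs_impute",
    "run_strategy",
    "stack_completed",
]

STRATEGIES = ("NRI", "IBD", "DTI")

_RIDGE = 1e-4  # jitter added to ill-conditioned information matrices
_ETA_CLIP = 35.0  # logistic linear predictor clip, avoids exp overflow


@dataclass(frozen=True)
class VariableSpec:
    """One column of the imputation model."""

    name: str
    kind: str  # "continuous" | "binary"
    imputed: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


@dataclass(frozen=True)
class ImputationModelSpec:
    """Strategy and FCS configuration.

    ``predictors`` optionally restricts the conditional model of a variable
    to a subset of the other columns; by default every variable is predicted
    from all others.  ``dti_exclude_endpoint`` drops the final outcome from
    the responder indicator's conditional model (sensitivity switch; the
    default keeps it in).
    """

    strategy: str = "IBD"
    include_cv: bool = False
    include_ae: bool = False
    M: int = 30
    cycles: int = 10
    dti_exclude_endpoint: bool = False
    predictors: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.strategy != "NRI" and self.M < 2:
            raise ValueError("multiple imputation requires M >= 2")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


@dataclass
class ImputationResult:
    """Completed responder vectors and per-imputation arm-difference estimates."""

    strategy: str
    completed_responders: np.ndarray  # (M, N) binary
    per_imputation: list[ArmProportionEstimate]
    fallback_events: int = 0

    @property
    def M(self) -> int:
        return self.completed_responders.shape[0]

    def estimates_and_ses(self) -> tuple[np.ndarray, np.ndarray]:
        est = np.array([e.diff for e in self.per_imputation])
        se = np.array([e.se for e in self.per_imputation])
        return est, se


def stack_completed(completed: list[dict[str, np.ndarray]]):
    """Stack M completed datasets into one long table with an imputation
    index column (standard stacked multiple-imputation format)."""
    import pandas as pd

    frames = []
    for m, cur in enumerate(completed, start=1):
        frame = pd.DataFrame(cur)
        frame.insert(0, "imputation", m)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def nri_impute(responders: np.ndarray) -> np.ndarray:
    """Set every undetermined responder status to non-responder (0)."""
    out = np.asarray(responders, dtype=float).copy()
    out[np.isnan(out)] = 0.0
    return out


# ---------------------------------------------------------------------------
# conditional-model fitting and posterior draws


def _design(cols: dict[str, np.ndarray], names: tuple[str, ...], rows=None) -> np.ndarray:
    n = next(iter(cols.values())).shape[0] if rows is None else int(np.sum(rows))
    X = np.empty((n, len(names) + 1))
    X[:, 0] = 1.0
    for k, name in enumerate(names):
        X[:, k + 1] = cols[name] if rows is None else cols[name][rows]
    return X


def _safe_cho(XtX: np.ndarray):
    """Cholesky factor of XtX, adding ridge jitter when rank-deficient."""
    try:
        return cho_factor(XtX, lower=True), False
    except np.linalg.LinAlgError:
        pass
    except ValueError:
        pass
    jitter = _RIDGE * max(np.mean(np.diag(XtX)), 1.0)
    return cho_factor(XtX + jitter * np.eye(XtX.shape[0]), lower=True), True


def _ols_fit(X: np.ndarray, y: np.ndarray):
    XtX = X.T @ X
    c, jittered = _safe_cho(XtX)
    beta = cho_solve(c, X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid), c, jittered


def impute_continuous_draw(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Proper Bayesian linear-regression imputation (flat priors).

    Draws the residual variance from its scaled inverse-chi-squared
    posterior, the coefficients from their conditional normal posterior, and
    the missing values as linear predictor plus fresh residual noise.
    Returns the imputed values and a flag marking a ridge fallback.
    """
    n_obs, p = X_obs.shape
    if n_obs < p + 2:
        raise ValueError(f"need at least {p + 2} observed rows for {p} parameters, got {n_obs}")
    beta_hat, sse, c, jittered = _ols_fit(X_obs, y_obs)
    df = n_obs - p
    sigma2 = max(sse, 1e-12) / rng.chisquare(df)
    sigma = np.sqrt(sigma2)
    # beta* ~ N(beta_hat, sigma2 * (X'X)^-1) via the stored Cholesky factor
    z = rng.standard_normal(p)
    beta = beta_hat + sigma * solve_triangular(c[0], z, lower=True, trans="T")
    return X_mis @ beta + sigma * rng.standard_normal(X_mis.shape[0]), jittered


def _irls_logistic(X: np.ndarray, y: np.ndarray, ridge, max_iter: int = 25):
    """Ridge-stabilized iteratively reweighted least squares.

    ``ridge`` is a scalar or per-coefficient penalty (prior precision) added
    to the information matrix.  Returns (beta, lower Cholesky of the
    penalized information, converged).  An unpenalized fit whose linear
    predictor saturates the clip bound is declared diverging (separation)
    and stopped early.
    """
    p = X.shape[1]
    penalty = np.diag(np.broadcast_to(np.asarray(ridge, dtype=float), (p,)))
    penalized = penalty.any()
    eye = np.eye(p)
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-6) / max(1.0 - y.mean(), 1e-6))
    info = eye
    converged = False
    for it in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        info = X.T @ (X * w[:, None]) + penalty
        score = X.T @ (y - mu) - penalty @ beta
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            info = info + _RIDGE * max(np.mean(np.diag(info)), 1.0) * eye
            step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-6:
            converged = True
            break
        if not penalized and it >= 2 and np.max(np.abs(eta)) >= _ETA_CLIP:
            break  # separation: coefficients diverging
    try:
        L = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(info + _RIDGE * max(np.mean(np.diag(info)), 1.0) * eye)
    return beta, L, converged


_PRIOR_SLOPE_SD = 2.5  # weakly-informative prior SD on standardized slopes
_PRIOR_INTERCEPT_SD = 10.0


def _penalized_logistic_draw(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Separation fallback: ridge prior on standardized coefficients.

    Fits the logistic model with a weakly-informative normal prior (SD 2.5
    on slopes of standardized predictors, SD 10 on the intercept) and draws
    coefficients from the Laplace approximation of that posterior.  Keeps
    both the mode and the draw covariance finite under (quasi-)complete
    separation, where the unpenalized information matrix collapses.
    """
    center = X_obs[:, 1:].mean(axis=0)
    scale = X_obs[:, 1:].std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs_obs = X_obs.copy()
    Xs_obs[:, 1:] = (X_obs[:, 1:] - center) / scale
    Xs_mis = X_mis.copy()
    Xs_mis[:, 1:] = (X_mis[:, 1:] - center) / scale
    tau = np.full(X_obs.shape[1], 1.0 / _PRIOR_SLOPE_SD**2)
    tau[0] = 1.0 / _PRIOR_INTERCEPT_SD**2
    beta, L, _ = _irls_logistic(Xs_obs, y_obs, ridge=tau, max_iter=50)
    z = rng.standard_normal(beta.shape[0])
    beta_draw = beta + solve_triangular(L, z, lower=True, trans="T")
    eta = np.clip(Xs_mis @ beta_draw, -_ETA_CLIP, _ETA_CLIP)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(X_mis.shape[0]) < prob).astype(float)


def impute_binary_draw(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Logistic-regression imputation with an asymptotic-normal parameter draw.

    On separation or non-convergence the fit is redone with a
    weakly-informative ridge prior on standardized coefficients; a one-class
    response short-circuits to a degenerate fill of the observed class.
    Returns imputed 0/1 values and a fallback flag.
    """
    ybar = y_obs.mean()
    if ybar in (0.0, 1.0):
        return np.full(X_mis.shape[0], ybar), True
    beta, L, converged = _irls_logistic(X_obs, y_obs, ridge=0.0)
    if not converged or not np.all(np.isfinite(beta)):
        logger.debug("logistic fit fell back to penalized draw (separation likely)")
        return _penalized_logistic_draw(X_obs, y_obs, X_mis, rng), True
    # beta* ~ N(beta_hat, info^-1) via the Cholesky factor of the information
    z = rng.standard_normal(beta.shape[0])
    beta_draw = beta + solve_triangular(L, z, lower=True, trans="T")
    eta = np.clip(X_mis @ beta_draw, -_ETA_CLIP, _ETA_CLIP)
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(X_mis.shape[0]) < prob).astype(float), False


# ---------------------------------------------------------------------------
# FCS engine


def _predictor_names(
    target: str, variables: list[VariableSpec], spec: ImputationModelSpec | None
) -> tuple[str, ...]:
    if spec is not None and spec.predictors is not None and target in spec.predictors:
        return tuple(spec.predictors[target])
    return tuple(v.name for v in variables if v.name != target)


def fill_in_start(
    cols: dict[str, np.ndarray],
    variables: list[VariableSpec],
    rng: np.random.Generator,
    spec: ImputationModelSpec | None = None,
) -> dict[str, np.ndarray]:
    """Sequential starting fills, in the order the variables are specified.

    Each partially observed variable is regressed (linear or logistic) on
    the columns that are complete at that point — the fully observed
    variables plus any earlier fills — and its missing entries are filled by
    prediction (continuous) or a Bernoulli draw at the fitted probability
    (binary).
    """
    out = {k: v.astype(float).copy() for k, v in cols.items()}
    for v in variables:
        y = out[v.name]
        miss = np.isnan(y)
        if not miss.any():
            continue
        obs = ~miss
        if not obs.any():
            raise ValueError(f"variable {v.name!r} has no observed values")
        candidates = _predictor_names(v.name, variables, spec)
        preds = tuple(p for p in candidates if not np.isnan(out[p]).any())
        X_obs = _design(out, preds, obs)
        X_mis = _design(out, preds, miss)
        if v.kind == "continuous":
            beta, _, _, _ = _ols_fit(X_obs, y[obs])
            y[miss] = X_mis @ beta
        else:
            yo = y[obs]
            if yo.mean() in (0.0, 1.0):
                y[miss] = yo.mean()
            else:
                beta, _, _ = _irls_logistic(X_obs, yo, ridge=0.0)
                if not np.all(np.isfinite(beta)):
                    beta, _, _ = _irls_logistic(X_obs, yo, ridge=_RIDGE)
                eta = np.clip(X_mis @ beta, -_ETA_CLIP, _ETA_CLIP)
                prob = 1.0 / (1.0 + np.exp(-eta))
                y[miss] = (rng.random(miss.sum()) < prob).astype(float)
    return out


def fcs_impute(
    cols: dict[str, np.ndarray],
    variables: list[VariableSpec],
    M: int = 30,
    cycles: int = 10,
    seed=None,
    spec: ImputationModelSpec | None = None,
) -> tuple[list[dict[str, np.ndarray]], int]:
    """Fully conditional specification: M completed copies of ``cols``.

    Every imputation runs on its own RNG substream: starting fills, then
    ``cycles`` full passes over the partially observed variables in order,
    refitting each conditional on the current completed data (rows where the
    target was actually observed) and redrawing its missing entries.
    Observed cells are never altered.  Returns the completed datasets and
    the number of fallback events encountered.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    miss_masks = {v.name: np.isnan(cols[v.name]) for v in variables}
    targets = [v for v in variables if miss_masks[v.name].any()]
    fallbacks = 0
    completed: list[dict[str, np.ndarray]] = []
    for sub in rng.spawn(M):
        cur = fill_in_start(cols, variables, sub, spec)
        for _ in range(cycles):
            for v in targets:
                miss = miss_masks[v.name]
                obs = ~miss
                preds = _predictor_names(v.name, variables, spec)
                X_obs = _design(cur, preds, obs)
                X_mis = _design(cur, preds, miss)
                draw = impute_continuous_draw if v.kind == "continuous" else impute_binary_draw
                cur[v.name][miss], fb = draw(X_obs, cols[v.name][obs], X_mis, sub)
                fallbacks += int(fb)
        completed.append(cur)
    return completed, fallbacks


# ---------------------------------------------------------------------------
# strategy runner


def _model_columns(
    data: TrialDataset, strategy: str, rule: ResponderRule, spec: ImputationModelSpec
) -> tuple[dict[str, np.ndarray], list[VariableSpec], ImputationModelSpec]:
    cols: dict[str, np.ndarray] = {"arm": data.arm.astype(float)}
    for j in range(N_VISITS):
        cols[f"Y{j + 1}"] = data.Y[:, j].astype(float)
    variables = [
        VariableSpec("arm", "binary", imputed=False),
        VariableSpec("Y1", "continuous", imputed=False),
        VariableSpec("Y2", "continuous"),
        VariableSpec("Y3", "continuous"),
        VariableSpec("Y4", "continuous"),
    ]
    if spec.include_cv:
        if data.cv is None:
            raise ValueError("include_cv requested but dataset has no CV column")
        cols["CV"] = data.cv.astype(float)
        variables.append(VariableSpec("CV", "continuous"))
    if spec.include_ae:
        if data.ae is None:
            raise ValueError("include_ae requested but dataset has no AE columns")
        for j in (1, 2, 3):
            cols[f"AE{j + 1}"] = data.ae[:, j].astype(float)
            variables.append(VariableSpec(f"AE{j + 1}", "binary"))
    if strategy == "DTI":
        cols["R"] = classify_responders(data, rule)
        variables.append(VariableSpec("R", "binary"))
        if spec.dti_exclude_endpoint and spec.predictors is None:
            others = tuple(v.name for v in variables if v.name not in ("R", "Y4"))
            spec = replace(spec, predictors={"R": others})
    return cols, variables, spec


def run_strategy(
    data: TrialDataset,
    strategy: str,
    rule: ResponderRule = DEFAULT_RULE,
    spec: ImputationModelSpec | None = None,
    seed=None,
) -> ImputationResult:
    """Run one missing-data strategy on a masked dataset.

    ``data`` carries its missingness as NaNs (see ``dropout.mask_dataset``).
    NRI returns a single completed responder vector; the MI strategies
    return ``spec.M`` completed vectors with per-imputation estimates of the
    arm difference in responder proportions.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if spec is None:
        spec = ImputationModelSpec(strategy=strategy)
    elif spec.strategy != strategy:
        spec = replace(spec, strategy=strategy)

    if strategy == "NRI":
        completed = nri_impute(classify_responders(data, rule))
        est = diff_proportions(completed, data.arm)
        return ImputationResult(
            strategy="NRI",
            completed_responders=completed[None, :],
            per_imputation=[est],
        )

    cols, variables, spec = _model_columns(data, strategy, rule, spec)
    completed_sets, fallbacks = fcs_impute(
        cols, variables, M=spec.M, cycles=spec.cycles, seed=seed, spec=spec
    )
    responders = np.empty((spec.M, data.n))
    estimates = []
    for m, cur in enumerate(completed_sets):
        if strategy == "IBD":
            change = cur[f"Y{rule.endpoint_index + 1}"] - cur[f"Y{rule.baseline_index + 1}"]
            r = (change >= rule.threshold).astype(float)
        else:
            r = cur["R"]
        responders[m] = r
        estimates.append(diff_proportions(r, data.arm))
    return ImputationResult(
        strategy=strategy,
        completed_responders=responders,
        per_imputation=estimates,
        fallback_events=fallbacks,
    )
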