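"""Difference-in-proportions estimation and Rubin's rules pooling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ArmProportionEstimate", "PooledEstimate", "diff_proportions", "rubin_pool"]

_SE_FLOOR = np.finfo(float).eps  # degenerate-SE guard for all-0/all-1 fixtures
_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ArmProportionEstimate:
    """Wald estimate of the arm difference in responder proportions."""

    p_A: float
    p_B: float
    se: float
    n_A: int
    n_B: int

    @property
    def diff(self) -> float:
        return self.p_A - self.p_B

    @property
    def ci(self) -> tuple[float, float]:
        return (self.diff - _Z975 * self.se, self.diff + _Z975 * self.se)

    @property
    def p_value(self) -> float:
        """Two-sided z-test of zero difference (unpooled Wald SE)."""
        z = self.diff / max(self.se, _SE_FLOOR)
        return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-combined difference in proportions."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    M: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def diff_proportions(responders: np.ndarray, arms: np.ndarray) -> ArmProportionEstimate:
    """Arm difference in responder proportions with the unpooled Wald SE.

    Every responder status must be determined (0/1); arm indicator 1 = A,
    0 = B.
    """
    responders = np.asarray(responders, dtype=float)
    arms = np.asarray(arms)
    if np.isnan(responders).any():
        raise ValueError("responder vector contains undetermined statuses")
    in_a = arms == 1
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both arms must be non-empty")
    p_a = float(responders[in_a].mean())
    p_b = float(responders[~in_a].mean())
    se = float(np.sqrt(p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b))
    return ArmProportionEstimate(p_A=p_a, p_B=p_b, se=se, n_A=n_a, n_B=n_b)


def rubin_pool(per_imputation: Sequence[tuple[float, float]]) -> PooledEstimate:
    """Combine M (estimate, SE) pairs by Rubin's rules.

    Pooled point estimate is the mean; total variance is the within-variance
    plus ``(1 + 1/M)`` times the between-variance; the degrees of freedom use
    the classic formula ``(M-1) * (1 + W / ((1 + 1/M) B))^2``, treated as
    infinite when the between-variance vanishes.  The CI and two-sided
    p-value use the t distribution on those df.
    """
    est = np.array([e for e, _ in per_imputation], dtype=float)
    se = np.array([s for _, s in per_imputation], dtype=float)
    M = est.shape[0]
    if M < 2:
        raise ValueError("Rubin pooling requires M >= 2 imputations")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(se))):
        raise ValueError("non-finite per-imputation estimates")
    qbar = float(est.mean())
    within = float(np.mean(se**2))
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / M) * between
    with np.errstate(over="ignore"):
        ratio = np.float64(within) / ((1.0 + 1.0 / M) * np.float64(between)) if between > 0 else np.inf
        df = float((M - 1) * (1.0 + ratio) ** 2)
    if np.isfinite(df):
        tq = stats.t.ppf(0.975, df)
        dist = stats.t(df)
    else:
        df = np.inf
        tq = _Z975
        dist = stats.norm
    se_tot = max(np.sqrt(total), _SE_FLOOR)
    p = float(2.0 * dist.sf(abs(qbar) / se_tot))
    return PooledEstimate(
        estimate=qbar,
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        ci_low=qbar - tq * np.sqrt(total),
        ci_high=qbar + tq * np.sqrt(total),
        p_value=p,
        M=M,
    )
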