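"""Simulation performance metrics.

All table-facing quantities are carried in percentage points: arm
proportions, differences, CIs, SEs and MSE are multiplied by 100 relative
to the internal fraction scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicateOutcome",
    "ScenarioMetrics",
    "percent_bias",
    "simulation_size",
    "summarize_scenario",
]


@dataclass(frozen=True)
class ReplicateOutcome:
    """One replicate's (possibly pooled) responder-difference inference.

    Everything on the fraction scale; conversion to percentage points
    happens in :func:`summarize_scenario`.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    p_A: float
    p_B: float


@dataclass(frozen=True)
class ScenarioMetrics:
    """Per-scenario, per-method summary (percentage-point scale)."""

    label: str
    n_sim: int
    mean_p_A: float
    mean_p_B: float
    mean_diff: float
    mean_ci_low: float
    mean_ci_high: float
    percent_bias: float | None
    coverage: float
    power: float
    mcse_bias: float
    mse: float
    se_mod: float
    se_emp: float
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def percent_bias(mean_p_A: float, mean_p_B: float, pi_A: float, pi_B: float) -> float:
    """Percent bias of the difference in proportions.

    ``((mean_p_A - mean_p_B) - (pi_A - pi_B)) / (pi_A - pi_B) * 100``;
    positive values are positive biases.  Any consistent scale works as long
    as the four arguments share it.
    """
    true_diff = pi_A - pi_B
    if true_diff == 0.0:
        raise ValueError("percent bias undefined for a zero true difference (null profile)")
    return ((mean_p_A - mean_p_B) - true_diff) / true_diff * 100.0


def simulation_size(sd_estimate: float, max_mcse: float) -> int:
    """Smallest replicate count with Monte-Carlo SE of bias at most ``max_mcse``.

    Solves ``sd / sqrt(n) <= max_mcse`` for integer n.
    """
    if sd_estimate <= 0 or max_mcse <= 0:
        raise ValueError("both inputs must be positive")
    tol = 1.0 + 1e-9  # guard against float noise in the squared ratio
    n = math.ceil((sd_estimate / max_mcse) ** 2 / tol)
    while sd_estimate / math.sqrt(n) > max_mcse * tol:
        n += 1
    while n > 1 and sd_estimate / math.sqrt(n - 1) <= max_mcse * tol:
        n -= 1
    return n


def summarize_scenario(
    outcomes: Sequence[ReplicateOutcome],
    pi_A: float,
    pi_B: float,
    label: str = "",
    n_failed: int = 0,
) -> ScenarioMetrics:
    """Aggregate replicate outcomes into the scenario metric set.

    ``pi_A``/``pi_B`` are the true responder rates on the fraction scale.
    Coverage counts CIs containing the true difference; power (or type-1
    error under a null profile) counts p-values below 0.05; percent bias is
    left as None when the true difference is zero.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    est = np.array([o.estimate for o in outcomes]) * 100.0
    se = np.array([o.se for o in outcomes]) * 100.0
    lo = np.array([o.ci_low for o in outcomes]) * 100.0
    hi = np.array([o.ci_high for o in outcomes]) * 100.0
    pv = np.array([o.p_value for o in outcomes])
    pa = np.array([o.p_A for o in outcomes]) * 100.0
    pb = np.array([o.p_B for o in outcomes]) * 100.0

    theta = (pi_A - pi_B) * 100.0
    n_sim = len(outcomes)
    se_emp = float(est.std(ddof=1))
    bias = (
        None
        if theta == 0.0
        else percent_bias(float(pa.mean()), float(pb.mean()), pi_A * 100.0, pi_B * 100.0)
    )
    return ScenarioMetrics(
        label=label,
        n_sim=n_sim,
        mean_p_A=float(pa.mean()),
        mean_p_B=float(pb.mean()),
        mean_diff=float(est.mean()),
        mean_ci_low=float(lo.mean()),
        mean_ci_high=float(hi.mean()),
        percent_bias=bias,
        coverage=float(np.mean((lo <= theta) & (theta <= hi))),
        power=float(np.mean(pv < 0.05)),
        mcse_bias=se_emp / math.sqrt(n_sim),
        mse=float(np.mean((est - theta) ** 2)),
        se_mod=float(se.mean()),
        se_emp=se_emp,
        n_failed=n_failed,
    )
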