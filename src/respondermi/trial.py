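"""Synthetic two-arm longitudinal trial generator.

Generates complete four-visit continuous outcomes from a random-intercept
model, an auxiliary covariate correlated with the final visit, and a
two-state adverse-event process; classifies responders on change from
baseline and provides the analytic true responder rates used as oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

N_VISITS = 4

__all__ = [
    "N_VISITS",
    "ResponseProfile",
    "VarianceComponents",
    "ResponderRule",
    "AEModel",
    "TrialDataset",
    "PROFILES",
    "DEFAULT_VARIANCE",
    "DEFAULT_RULE",
    "DEFAULT_AE_MODEL",
    "simulate_trial",
    "generate_cv",
    "generate_ae",
    "classify_responders",
    "true_response_rate",
]


@dataclass(frozen=True)
class ResponseProfile:
    """Mean trajectories over the four visits for arms A and B."""

    name: str
    mu_A: tuple[float, float, float, float]
    mu_B: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.mu_A) != N_VISITS or len(self.mu_B) != N_VISITS:
            raise ValueError("mean vectors must have length 4")
        if self.mu_A[0] != self.mu_B[0]:
            raise ValueError("arms must share a common baseline mean")

    def mean(self, arm: int, visit: int) -> float:
        """Population mean for ``arm`` (1 = A, 0 = B) at 0-based ``visit``."""
        return (self.mu_A if arm == 1 else self.mu_B)[visit]

    def mean_change(self, arm: int, baseline_index: int = 0, endpoint_index: int = 3) -> float:
        mu = self.mu_A if arm == 1 else self.mu_B
        return mu[endpoint_index] - mu[baseline_index]


#: The four published response profiles.  ``linear`` and ``nonlinear`` have a
#: 6-point arm difference in mean change at the final visit; ``null1`` and
#: ``null2`` have no difference and are used for type-1 error.
PROFILES: dict[str, ResponseProfile] = {
    "linear": ResponseProfile("linear", (65, 67, 69, 71), (65, 65, 65, 65)),
    "nonlinear": ResponseProfile("nonlinear", (65, 63, 68, 71), (65, 67, 66, 65)),
    "null1": ResponseProfile("null1", (65, 65, 65, 65), (65, 65, 65, 65)),
    "null2": ResponseProfile("null2", (65, 67, 69, 71), (65, 63, 68, 71)),
}


@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept SD and residual SD of the outcome model."""

    sigma_b: float = 12.0
    sigma_eps: float = 7.0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_eps <= 0:
            raise ValueError("sigma_b must be >= 0 and sigma_eps > 0")

    @property
    def icc(self) -> float:
        """Compound-symmetry within-person correlation."""
        v = self.sigma_b**2
        return v / (v + self.sigma_eps**2)

    @property
    def change_sd(self) -> float:
        """SD of the endpoint-minus-baseline change (intercept cancels)."""
        return float(np.sqrt(2.0) * self.sigma_eps)


DEFAULT_VARIANCE = VarianceComponents()


@dataclass(frozen=True)
class ResponderRule:
    """Responder = change from baseline to endpoint at least ``threshold``."""

    threshold: float = 12.4
    baseline_index: int = 0
    endpoint_index: int = 3

    def __post_init__(self) -> None:
        if not self.endpoint_index > self.baseline_index:
            raise ValueError("endpoint_index must exceed baseline_index")


DEFAULT_RULE = ResponderRule()


@dataclass(frozen=True)
class AEModel:
    """First-order Markov adverse-event process.

    ``p_init_A``/``p_init_B`` give P(AE=1) at the first post-baseline visit;
    ``conditional`` maps ``(visit, arm, previous_ae)`` (0-based visit index,
    arm 1 = A / 0 = B) to P(AE=1) at visits 3 and 4.  No AEs occur at
    baseline.
    """

    p_init_A: float = 0.3
    p_init_B: float = 0.5
    conditional: dict[tuple[int, int, int], float] = field(
        default_factory=lambda: {
            (2, 1, 0): 0.2, (2, 1, 1): 0.8, (2, 0, 0): 0.4, (2, 0, 1): 0.8,
            (3, 1, 0): 0.1, (3, 1, 1): 0.8, (3, 0, 0): 0.2, (3, 0, 1): 0.8,
        }
    )

    def __post_init__(self) -> None:
        probs = [self.p_init_A, self.p_init_B, *self.conditional.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("AE probabilities must lie in [0, 1]")
        required = {(j, arm, g) for j in (2, 3) for arm in (0, 1) for g in (0, 1)}
        missing = required - set(self.conditional)
        if missing:
            raise ValueError(f"AE conditional table missing cells: {sorted(missing)}")


DEFAULT_AE_MODEL = AEModel()


@dataclass
class TrialDataset:
    """Complete (or supplied) wide-format trial data.

    Attributes
    ----------
    arm : (N,) int array, 1 for treatment A and 0 for treatment B.
    Y : (N, 4) float array of continuous outcomes.
    cv : optional (N,) auxiliary covariate.
    ae : optional (N, 4) binary adverse-event indicators (baseline all 0).
    """

    arm: np.ndarray
    Y: np.ndarray
    cv: np.ndarray | None = None
    ae: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=int)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != N_VISITS:
            raise ValueError("Y must be an N x 4 matrix")
        if self.arm.shape != (self.Y.shape[0],):
            raise ValueError("arm and Y row counts disagree")
        if self.cv is not None:
            self.cv = np.asarray(self.cv, dtype=float)
        if self.ae is not None:
            self.ae = np.asarray(self.ae, dtype=float)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            arm=self.arm.copy(),
            Y=self.Y.copy(),
            cv=None if self.cv is None else self.cv.copy(),
            ae=None if self.ae is None else self.ae.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide-format table: subject_id, arm, Y1..Y4, CV, AE1..AE4."""
        out = {"subject_id": np.arange(1, self.n + 1), "arm": self.arm}
        for j in range(N_VISITS):
            out[f"Y{j + 1}"] = self.Y[:, j]
        if self.cv is not None:
            out["CV"] = self.cv
        if self.ae is not None:
            for j in range(N_VISITS):
                out[f"AE{j + 1}"] = self.ae[:, j]
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDataset":
        ycols = [f"Y{j + 1}" for j in range(N_VISITS)]
        cv = frame["CV"].to_numpy(float) if "CV" in frame else None
        aecols = [f"AE{j + 1}" for j in range(N_VISITS)]
        ae = frame[aecols].to_numpy(float) if set(aecols) <= set(frame) else None
        return cls(arm=frame["arm"].to_numpy(int), Y=frame[ycols].to_numpy(float), cv=cv, ae=ae)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        return cls.from_frame(pd.read_csv(path))


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trial(
    profile: ResponseProfile,
    n: int = 200,
    var: VarianceComponents = DEFAULT_VARIANCE,
    seed=None,
) -> TrialDataset:
    """Simulate a complete trial: shared-intercept normal outcomes.

    Each outcome is the profile mean for the subject's arm and visit plus a
    subject-level intercept ``N(0, sigma_b^2)`` and independent visit noise
    ``N(0, sigma_eps^2)``.  Allocation is exactly 1:1: the first ``n/2``
    subjects are arm A (indicator 1), the rest arm B.
    """
    if n % 2 != 0 or n < 4:
        raise ValueError(f"n must be even and >= 4, got {n}")
    rng = _resolve_rng(seed)
    half = n // 2
    arm = np.concatenate([np.ones(half, dtype=int), np.zeros(half, dtype=int)])
    means = np.where(arm[:, None] == 1, profile.mu_A, profile.mu_B)
    b = rng.normal(0.0, var.sigma_b, size=n)
    eps = rng.normal(0.0, var.sigma_eps, size=(n, N_VISITS))
    return TrialDataset(arm=arm, Y=means + b[:, None] + eps)


def generate_cv(
    data: TrialDataset,
    rho: float = 0.3,
    mean: float = 38.0,
    sd: float = 62.7,
    profile: ResponseProfile | None = None,
    var: VarianceComponents = DEFAULT_VARIANCE,
    seed=None,
) -> TrialDataset:
    """Append an auxiliary covariate jointly normal with the final outcome.

    Uses the conditional-normal construction
    ``CV = mean + sd * (rho * z + sqrt(1 - rho^2) * e)`` where ``z``
    standardizes Y4 by its population moments under the equal-allocation
    two-arm mixture, so the pooled population correlation with Y4 equals
    ``rho`` exactly.  When ``profile`` is omitted Y4 is standardized by its
    empirical pooled moments.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = _resolve_rng(seed)
    y4 = data.Y[:, N_VISITS - 1]
    if profile is not None:
        mu4 = 0.5 * (profile.mu_A[-1] + profile.mu_B[-1])
        between = 0.25 * (profile.mu_A[-1] - profile.mu_B[-1]) ** 2
        sd4 = np.sqrt(var.sigma_b**2 + var.sigma_eps**2 + between)
    else:
        mu4 = y4.mean()
        sd4 = y4.std(ddof=1)
    z = (y4 - mu4) / sd4
    e = rng.normal(size=data.n)
    out = data.copy()
    out.cv = mean + sd * (rho * z + np.sqrt(1.0 - rho**2) * e)
    return out


def generate_ae(
    data: TrialDataset,
    model: AEModel = DEFAULT_AE_MODEL,
    seed=None,
) -> TrialDataset:
    """Append the Markov adverse-event series (baseline AE identically 0)."""
    rng = _resolve_rng(seed)
    n = data.n
    ae = np.zeros((n, N_VISITS))
    p2 = np.where(data.arm == 1, model.p_init_A, model.p_init_B)
    ae[:, 1] = rng.random(n) < p2
    for j in (2, 3):
        p = np.array(
            [model.conditional[(j, a, int(g))] for a, g in zip(data.arm, ae[:, j - 1])]
        )
        ae[:, j] = rng.random(n) < p
    out = data.copy()
    out.ae = ae
    return out


def classify_responders(data: TrialDataset, rule: ResponderRule = DEFAULT_RULE) -> np.ndarray:
    """Responder indicators; NaN marks undetermined (missing endpoint/baseline).

    The threshold is inclusive: change >= threshold counts as response.
    """
    change = data.Y[:, rule.endpoint_index] - data.Y[:, rule.baseline_index]
    out = np.where(change >= rule.threshold, 1.0, 0.0)
    out[np.isnan(change)] = np.nan
    return out


def true_response_rate(
    profile: ResponseProfile,
    arm: int,
    rule: ResponderRule = DEFAULT_RULE,
    var: VarianceComponents = DEFAULT_VARIANCE,
) -> float:
    """Analytic responder probability for one arm.

    The change score drops the shared intercept, so it is normal with mean
    equal to the arm's mean change and SD ``sqrt(2) * sigma_eps``; the rate is
    the upper tail at the threshold.
    """
    delta = profile.mean_change(arm, rule.baseline_index, rule.endpoint_index)
    return float(norm.sf(rule.threshold - delta, scale=var.change_sd))
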