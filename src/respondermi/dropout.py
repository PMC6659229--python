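"""Monotone MAR dropout engine.

Implements the six dropout propensity models and the scaled-propensity
thresholding mechanism: at each post-baseline visit, every subject still on
study drops out when an independent Uniform(0,1) draw falls below the
scenario cutoff times their dropout propensity — so the per-visit dropout
probability stays proportional to the propensity model, and a single cutoff
scales all six models to the target endpoint missingness rate (30% or
50%).  The cutoff is calibrated by bisection on pilot replicates.  All propensities depend only on the observed history (previous-visit
outcome, arm, current adverse-event status), so the mechanism is missing at
random by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .trial import N_VISITS, TrialDataset

__all__ = [
    "DropoutSpec",
    "MissingnessMask",
    "propensity",
    "apply_dropout",
    "calibrate_cutoff",
    "mask_dataset",
]

VALID_MODELS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class DropoutSpec:
    """Configuration of one dropout mechanism.

    model_id
        1: lack of efficacy, probit-type propensity on the previous outcome.
        2: arm-differing mechanisms (A drops when low, B when high).
        3: model 2 with the arms reversed.
        4: model 1 with arm-specific weights (differential dropout rates).
        5: logistic propensity on the previous outcome.
        6: logistic propensity on the previous outcome and current AE status.
    """

    model_id: int = 1
    target_rate: float = 0.30
    weight_A: float = 0.3
    weight_B: float = 1.0
    b1: float = 0.01
    b2: float = -0.40

    def __post_init__(self) -> None:
        if self.model_id not in VALID_MODELS:
            raise ValueError(f"unknown dropout model_id {self.model_id}")
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must lie in (0, 1)")
        if self.weight_A <= 0 or self.weight_B <= 0:
            raise ValueError("arm weights must be positive")


@dataclass
class MissingnessMask:
    """Monotone observation indicators plus bookkeeping.

    ``Z[i, j] == 0`` means Y_ij is missing; baseline is always observed.
    ``dropout_time[i]`` is the 0-based first missing visit, or -1 if the
    subject completes the study.
    """

    Z: np.ndarray
    dropout_time: np.ndarray
    achieved_rate: float
    cutoff: float
    model_id: int

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=int)
        if np.any(self.Z[:, 0] == 0):
            raise ValueError("baseline must always be observed")
        # monotone: once missing, missing thereafter
        if np.any(np.diff(self.Z, axis=1) > 0):
            raise ValueError("mask is not monotone")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.Z, columns=[f"Z{j + 1}" for j in range(N_VISITS)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def propensity(
    model_id: int,
    data: TrialDataset,
    j: int,
    spec: DropoutSpec,
    at_risk: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subject dropout propensity at 0-based visit ``j``.

    Returns an array aligned with the at-risk subjects (all subjects when
    ``at_risk`` is None).  The probit-type models standardize the
    previous-visit outcome by its empirical mean and SD pooled over both arms
    among subjects still at risk.
    """
    if model_id not in VALID_MODELS:
        raise ValueError(f"unknown dropout model_id {model_id}")
    if j < 1:
        raise ValueError("dropout cannot occur at baseline")
    if at_risk is None:
        at_risk = np.ones(data.n, dtype=bool)
    prev = data.Y[at_risk, j - 1]
    arm = data.arm[at_risk]

    if model_id in (1, 2, 3, 4):
        phi = norm.cdf(prev, loc=prev.mean(), scale=prev.std(ddof=1))
        if model_id == 1:
            return 1.0 - phi
        if model_id == 2:
            return np.where(arm == 1, 1.0 - phi, phi)
        if model_id == 3:
            return np.where(arm == 1, phi, 1.0 - phi)
        w = np.where(arm == 1, spec.weight_A, spec.weight_B)
        return w * (1.0 - phi)
    if model_id == 5:
        return 1.0 / (1.0 + np.exp(spec.b1 * prev))
    if data.ae is None:
        raise ValueError("dropout model 6 requires adverse-event columns")
    return 1.0 / (1.0 + np.exp(spec.b1 * prev + spec.b2 * data.ae[at_risk, j]))


def _run_process(
    data: TrialDataset, spec: DropoutSpec, cutoff: float, uniforms: np.ndarray
) -> np.ndarray:
    """Sequential dropout given pre-drawn uniforms; returns dropout_time."""
    n = data.n
    dropout_time = np.full(n, -1, dtype=int)
    at_risk = np.ones(n, dtype=bool)
    for j in range(1, N_VISITS):
        if not at_risk.any():
            break
        p = propensity(spec.model_id, data, j, spec, at_risk)
        dropped = np.where(at_risk)[0][uniforms[at_risk, j - 1] < cutoff * p]
        dropout_time[dropped] = j
        at_risk[dropped] = False
    return dropout_time


def _mask_from_times(dropout_time: np.ndarray) -> np.ndarray:
    n = dropout_time.shape[0]
    visits = np.arange(N_VISITS)
    t = np.where(dropout_time < 0, N_VISITS, dropout_time)
    return (visits[None, :] < t[:, None]).astype(int)


def apply_dropout(
    data: TrialDataset,
    spec: DropoutSpec,
    seed=None,
    cutoff: float | None = None,
    calibration_replicates: int = 200,
    tolerance: float = 0.005,
) -> MissingnessMask:
    """Impose monotone dropout on a complete dataset.

    When ``cutoff`` is not supplied it is calibrated on the fly against this
    dataset using ``calibration_replicates`` fresh uniform draws (scenario
    runners calibrate once on pilot datasets and pass the frozen cutoff).
    """
    if np.isnan(data.Y).any():
        raise ValueError("apply_dropout expects a complete dataset")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if cutoff is None:
        pilot_rng = np.random.default_rng(rng.integers(2**63))
        cutoff = calibrate_cutoff(
            [data] * calibration_replicates,
            spec,
            spec.target_rate,
            tolerance=tolerance,
            seed=pilot_rng,
        )
    uniforms = rng.random((data.n, N_VISITS - 1))
    dropout_time = _run_process(data, spec, cutoff, uniforms)
    Z = _mask_from_times(dropout_time)
    achieved = float(np.mean(Z[:, N_VISITS - 1] == 0))
    return MissingnessMask(
        Z=Z,
        dropout_time=dropout_time,
        achieved_rate=achieved,
        cutoff=cutoff,
        model_id=spec.model_id,
    )


def calibrate_cutoff(
    pilot_datasets: Sequence[TrialDataset],
    spec: DropoutSpec,
    target_rate: float | None = None,
    tolerance: float = 0.005,
    seed=None,
    max_iter: int = 60,
) -> float:
    """Bisection search for the propensity scaling hitting the target rate.

    Uses common random numbers: the pilot uniforms are drawn once and reused
    at every candidate cutoff, making the mean achieved endpoint-missingness
    rate a monotone non-decreasing step function of the cutoff.  Stops when
    the mean achieved rate is within ``tolerance`` of the target.
    """
    if target_rate is None:
        target_rate = spec.target_rate
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    uniforms = [rng.random((d.n, N_VISITS - 1)) for d in pilot_datasets]

    def achieved(cut: float) -> float:
        rates = []
        for d, u in zip(pilot_datasets, uniforms):
            t = _run_process(d, spec, cut, u)
            rates.append(np.mean(t >= 0))
        return float(np.mean(rates))

    lo, hi = 0.0, 1.0
    for _ in range(40):  # expand until the target is bracketed
        if achieved(hi) >= target_rate:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError(
            f"target rate {target_rate} not bracketed: achieved only "
            f"{achieved(hi):.3f} at cutoff {hi:g}"
        )
    cut = 0.5 * (lo + hi)
    for _ in range(max_iter):
        cut = 0.5 * (lo + hi)
        r = achieved(cut)
        if abs(r - target_rate) <= tolerance:
            return cut
        if r < target_rate:
            lo = cut
        else:
            hi = cut
    raise RuntimeError(
        f"calibration failed to reach target {target_rate} within tolerance "
        f"{tolerance}; last achieved {r:.4f} at cutoff {cut:.6f}"
    )


def mask_dataset(data: TrialDataset, mask: MissingnessMask) -> TrialDataset:
    """Apply a mask: masked outcomes become NaN.

    For the adverse-event series, AEs strictly after the dropout visit are
    also set to missing (the AE at the dropout visit itself is part of the
    observed history that drove the dropout).
    """
    out = data.copy()
    out.Y[mask.Z == 0] = np.nan
    if out.ae is not None:
        t = mask.dropout_time
        visits = np.arange(N_VISITS)
        ae_missing = (t[:, None] >= 0) & (visits[None, :] > t[:, None])
        out.ae[ae_missing] = np.nan
    return out
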