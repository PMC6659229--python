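"""Scenario and study orchestration.

A scenario is one cell of the simulation factorial: a response profile, a
dropout mechanism, a target missingness rate, and a set of missing-data
strategy variants evaluated on the same replicate datasets.  The study
runner executes the full factorial and emits table-shaped summaries.

RNG layout: a master seed spawns one child sequence per scenario; each
scenario spawns one calibration stream plus one stream per replicate; each
replicate stream drives data generation, dropout, and per-variant
imputation in a fixed documented order, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dropout import DropoutSpec, apply_dropout, calibrate_cutoff, mask_dataset
from .impute import ImputationModelSpec, run_strategy
from .metrics import ReplicateOutcome, ScenarioMetrics, summarize_scenario
from .pooling import diff_proportions, rubin_pool
from .trial import (
    DEFAULT_AE_MODEL,
    PROFILES,
    AEModel,
    ResponderRule,
    VarianceComponents,
    classify_responders,
    generate_ae,
    generate_cv,
    simulate_trial,
    true_response_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyVariant",
    "ScenarioConfig",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_study",
    "default_variants",
    "default_study_configs",
    "load_config",
]

#: default imputation counts keyed by missingness rate
DEFAULT_M = {0.30: 30, 0.50: 50}


@dataclass(frozen=True)
class StrategyVariant:
    """A strategy plus its auxiliary-variable flags."""

    strategy: str
    include_cv: bool = False
    include_ae: bool = False

    @property
    def label(self) -> str:
        base = {"NRI": "NRI", "DTI": "DTI MI", "IBD": "IBD MI"}[self.strategy]
        if self.include_cv:
            base += " with CV"
        if self.include_ae:
            base += " with AE"
        return base


def default_variants(model_id: int) -> tuple[StrategyVariant, ...]:
    """The published method set for a dropout model (AE variants for model 6)."""
    variants = [
        StrategyVariant("NRI"),
        StrategyVariant("DTI"),
        StrategyVariant("DTI", include_cv=True),
        StrategyVariant("IBD"),
        StrategyVariant("IBD", include_cv=True),
    ]
    if model_id == 6:
        variants.insert(3, StrategyVariant("DTI", include_ae=True))
        variants.append(StrategyVariant("IBD", include_ae=True))
    return tuple(variants)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario."""

    profile: str = "linear"
    n: int = 200
    sigma_b: float = 12.0
    sigma_eps: float = 7.0
    threshold: float = 12.4
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    variants: tuple[StrategyVariant, ...] = (StrategyVariant("NRI"),)
    n_sim: int = 1600
    M: int | None = None
    cycles: int = 10
    cv_rho: float = 0.3
    cv_mean: float = 38.0
    cv_sd: float = 62.7
    ae_model: AEModel = field(default_factory=lambda: DEFAULT_AE_MODEL)
    pilot_replicates: int = 200
    calibration_tolerance: float = 0.005
    true_rates: tuple[float, float] | None = None
    dti_exclude_endpoint: bool = False
    base_seed: int | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.n_sim < 2:
            raise ValueError("n_sim must be >= 2")

    @property
    def profile_obj(self):
        return PROFILES[self.profile]

    @property
    def var(self) -> VarianceComponents:
        return VarianceComponents(self.sigma_b, self.sigma_eps)

    @property
    def rule(self) -> ResponderRule:
        return ResponderRule(self.threshold)

    @property
    def m_imputations(self) -> int:
        if self.M is not None:
            return self.M
        return DEFAULT_M.get(round(self.dropout.target_rate, 2), 30)

    @property
    def needs_ae(self) -> bool:
        return self.dropout.model_id == 6 or any(v.include_ae for v in self.variants)

    def resolve_true_rates(self) -> tuple[float, float]:
        """Fractions; analytic oracle unless overridden in the config."""
        if self.true_rates is not None:
            return self.true_rates
        prof, var, rule = self.profile_obj, self.var, self.rule
        return (
            true_response_rate(prof, 1, rule, var),
            true_response_rate(prof, 0, rule, var),
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        raw = dict(raw)
        if "dropout" in raw and isinstance(raw["dropout"], dict):
            raw["dropout"] = DropoutSpec(**raw["dropout"])
        if "variants" in raw:
            raw["variants"] = tuple(
                v if isinstance(v, StrategyVariant) else StrategyVariant(**v)
                for v in raw["variants"]
            )
        if "ae_model" in raw and isinstance(raw["ae_model"], dict):
            ae = dict(raw["ae_model"])
            if "conditional" in ae:
                ae["conditional"] = {
                    tuple(int(x) for x in str(k).split(",")): float(p)
                    for k, p in ae["conditional"].items()
                }
            raw["ae_model"] = AEModel(**ae)
        if "true_rates" in raw and raw["true_rates"] is not None:
            raw["true_rates"] = tuple(raw["true_rates"])
        return cls(**raw)


def load_config(path) -> ScenarioConfig:
    """Read a scenario config from a YAML (or JSON) file."""
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


@dataclass
class ScenarioResult:
    """Replicate-level outcomes and summaries for every variant of a scenario."""

    config: ScenarioConfig
    cutoff: float
    pi_A: float
    pi_B: float
    outcomes: dict[str, list[ReplicateOutcome]]
    metrics: dict[str, ScenarioMetrics]
    n_failed: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, m in self.metrics.items():
            row = {
                "profile": self.config.profile,
                "dropout_model": self.config.dropout.model_id,
                "missing_rate": self.config.dropout.target_rate,
                "method": label,
            }
            row.update(m.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def replicate_frame(self) -> pd.DataFrame:
        rows = []
        for label, outs in self.outcomes.items():
            for r, o in enumerate(outs):
                rows.append(
                    {
                        "method": label,
                        "replicate": r,
                        "estimate": o.estimate,
                        "se": o.se,
                        "ci_low": o.ci_low,
                        "ci_high": o.ci_high,
                        "p_value": o.p_value,
                        "p_A": o.p_A,
                        "p_B": o.p_B,
                    }
                )
        return pd.DataFrame(rows)


def _full_data_outcome(data, rule) -> ReplicateOutcome:
    est = diff_proportions(classify_responders(data, rule), data.arm)
    lo, hi = est.ci
    return ReplicateOutcome(est.diff, est.se, lo, hi, est.p_value, est.p_A, est.p_B)


def _variant_outcome(masked, variant, config, seed) -> ReplicateOutcome:
    spec = ImputationModelSpec(
        strategy=variant.strategy,
        include_cv=variant.include_cv,
        include_ae=variant.include_ae,
        M=config.m_imputations if variant.strategy != "NRI" else 30,
        cycles=config.cycles,
        dti_exclude_endpoint=config.dti_exclude_endpoint,
    )
    result = run_strategy(masked, variant.strategy, config.rule, spec, seed=seed)
    if variant.strategy == "NRI":
        e = result.per_imputation[0]
        lo, hi = e.ci
        return ReplicateOutcome(e.diff, e.se, lo, hi, e.p_value, e.p_A, e.p_B)
    pooled = rubin_pool([(e.diff, e.se) for e in result.per_imputation])
    p_a = float(np.mean([e.p_A for e in result.per_imputation]))
    p_b = float(np.mean([e.p_B for e in result.per_imputation]))
    return ReplicateOutcome(
        pooled.estimate, pooled.se, pooled.ci_low, pooled.ci_high, pooled.p_value, p_a, p_b
    )


def simulate_complete(config: ScenarioConfig, rng: np.random.Generator):
    """One complete dataset per the scenario config (CV and AE included)."""
    data = simulate_trial(config.profile_obj, config.n, config.var, seed=rng)
    data = generate_cv(
        data, config.cv_rho, config.cv_mean, config.cv_sd,
        profile=config.profile_obj, var=config.var, seed=rng,
    )
    if config.needs_ae:
        data = generate_ae(data, config.ae_model, seed=rng)
    return data


def run_replicate(
    config: ScenarioConfig, cutoff: float, seed
) -> dict[str, ReplicateOutcome]:
    """One replicate: simulate, mask, run every variant; returns label -> outcome.

    The ``Full`` label carries the complete-data analysis.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = simulate_complete(config, rng)
    mask = apply_dropout(data, config.dropout, seed=rng, cutoff=cutoff)
    masked = mask_dataset(data, mask)
    out = {"Full": _full_data_outcome(data, config.rule)}
    for variant, sub in zip(config.variants, rng.spawn(len(config.variants))):
        out[variant.label] = _variant_outcome(masked, variant, config, sub)
    return out


def calibrate_scenario(config: ScenarioConfig, seed) -> float:
    """Frozen scenario-level dropout cutoff from pilot replicates."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pilots = [simulate_complete(config, rng) for _ in range(config.pilot_replicates)]
    return calibrate_cutoff(
        pilots,
        config.dropout,
        tolerance=config.calibration_tolerance,
        seed=rng,
    )


def run_scenario(config: ScenarioConfig, seed=None, max_failure_rate: float = 0.01) -> ScenarioResult:
    """Run all replicates of one scenario and summarize every variant.

    ``seed`` falls back to the config's ``base_seed`` when omitted.
    """
    if seed is None:
        seed = config.base_seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    calib_seed, *rep_seeds = ss.spawn(config.n_sim + 1)
    cutoff = calibrate_scenario(config, np.random.default_rng(calib_seed))

    labels = ["Full"] + [v.label for v in config.variants]
    outcomes: dict[str, list[ReplicateOutcome]] = {k: [] for k in labels}
    n_failed = 0
    for r, rep_seed in enumerate(rep_seeds):
        try:
            rep = run_replicate(config, cutoff, np.random.default_rng(rep_seed))
        except Exception:
            n_failed += 1
            logger.exception("replicate %d failed", r)
            if n_failed > max(1, max_failure_rate * config.n_sim):
                raise RuntimeError(
                    f"scenario aborted: {n_failed} replicate failures "
                    f"(> {max_failure_rate:.0%} of {config.n_sim})"
                )
            continue
        for k, o in rep.items():
            outcomes[k].append(o)

    pi_a, pi_b = config.resolve_true_rates()
    metrics = {
        k: summarize_scenario(v, pi_a, pi_b, label=k, n_failed=n_failed)
        for k, v in outcomes.items()
    }
    return ScenarioResult(
        config=config,
        cutoff=cutoff,
        pi_A=pi_a,
        pi_B=pi_b,
        outcomes=outcomes,
        metrics=metrics,
        n_failed=n_failed,
    )


def default_study_configs(
    n_sim: int = 1600,
    profiles: tuple[str, ...] = ("linear", "nonlinear"),
    models: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    rates: tuple[float, ...] = (0.30, 0.50),
    null_profiles: tuple[str, ...] = ("null1", "null2"),
    null_models: tuple[int, ...] = (1, 4),
    cycles: int = 10,
) -> list[ScenarioConfig]:
    """The published factorial: effect profiles x 6 models x 2 rates, plus
    the type-1-error cells (null profiles x models 1 and 4 at 30%)."""
    configs = []
    for profile in profiles:
        for model in models:
            for rate in rates:
                configs.append(
                    ScenarioConfig(
                        profile=profile,
                        dropout=DropoutSpec(model_id=model, target_rate=rate),
                        variants=default_variants(model),
                        n_sim=n_sim,
                        cycles=cycles,
                    )
                )
    for profile in null_profiles:
        for model in null_models:
            configs.append(
                ScenarioConfig(
                    profile=profile,
                    dropout=DropoutSpec(model_id=model, target_rate=0.30),
                    variants=default_variants(model),
                    n_sim=n_sim,
                    cycles=cycles,
                )
            )
    return configs


def run_study(
    configs: list[ScenarioConfig],
    seed=None,
    out_dir=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a list of scenarios on spawned seed streams; optionally write
    summary/replicate CSVs and a JSON metrics file to ``out_dir``."""
    ss = np.random.SeedSequence(seed)
    frames = []
    results = []
    for config, child in zip(configs, ss.spawn(len(configs))):
        if progress:
            print(
                f"scenario: profile={config.profile} model={config.dropout.model_id} "
                f"rate={config.dropout.target_rate} n_sim={config.n_sim}",
                flush=True,
            )
        res = run_scenario(config, seed=child)
        results.append(res)
        frames.append(res.summary_frame())
    summary = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        payload = []
        for res in results:
            payload.append(
                {
                    "profile": res.config.profile,
                    "dropout_model": res.config.dropout.model_id,
                    "missing_rate": res.config.dropout.target_rate,
                    "cutoff": res.cutoff,
                    "pi_A": res.pi_A,
                    "pi_B": res.pi_B,
                    "metrics": {k: m.to_dict() for k, m in res.metrics.items()},
                }
            )
            tag = (
                f"{res.config.profile}_m{res.config.dropout.model_id}"
                f"_r{int(round(res.config.dropout.target_rate * 100))}"
            )
            res.replicate_frame().to_csv(out / f"replicates_{tag}.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    return summary
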