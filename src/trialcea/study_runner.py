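"""Scenario orchestration: base case, sensitivity analyses, design statistics.

A scenario runs the whole pipeline on a trial cohort: cost breakdowns per
wave, imputation of follow-up outcomes and cost subtotals, responder/QALY
effects, and the bootstrapped SUR estimation with its quadrant shares and
acceptability curve.  The closed scenario set mirrors the usual sensitivity
grid of a trial-based economic evaluation:

* ``main`` — societal perspective, PMM multiple imputation, baseline
  adjustment (productivity costs in the cost equation, baseline IDS-SR in
  the effect equation);
* ``paid_job_only`` — restrict to participants in paid employment before
  imputation;
* ``no_baseline_adjust`` — drop the baseline covariates from both equations;
* ``healthcare_perspective`` — exclude patient/family costs and productivity
  losses;
* ``opportunity_costs`` — add the participants' own time to the intervention
  cost;
* ``regression_imputation`` and ``locf`` — alternative imputation strategies.

The comparative horizon is 3 months (the control arm receives the
intervention afterwards); a 6-month run is offered descriptively only and
flagged non-comparative.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cea_engine, costing, missing_data, outcomes
from .cea_engine import BootstrapCloud, CeaDesign, CeacCurve, QuadrantShares
from .costing import FrictionParams, UnitPriceTable
from .missing_data import ImputationConfig, ImputedDatasets
from .trial_data import ARM_CDMI, ParticipantRecord, WAVES

SCENARIOS = (
    "main",
    "paid_job_only",
    "no_baseline_adjust",
    "healthcare_perspective",
    "opportunity_costs",
    "regression_imputation",
    "locf",
)
EFFECT_KINDS = ("responder_rate", "qaly")


@dataclass
class ScenarioConfig:
    scenario_id: str = "main"
    effect_kind: str = "responder_rate"
    horizon_months: int = 3
    wtp_grid: np.ndarray = field(
        default_factory=lambda: cea_engine.DEFAULT_WTP_GRID.copy()
    )
    B: int = 5000
    m: int = 5
    pmm_donors: int = 5
    seed: int = 0
    #: utility difference per effect-size unit; required for QALY effects
    conversion_factor: float | None = None
    annual_platform_cost: float = 19_500.0
    annual_accounts: int = 5_000
    opportunity_hours: float = 3.5
    opportunity_hourly_wage: float = 14.0
    ref_year: int = 2016
    qaly_method: str = "auc"

    def validate(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ValueError(f"unknown scenario: {self.scenario_id}")
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind: {self.effect_kind}")
        if self.horizon_months not in (3, 6):
            raise ValueError("horizon_months must be 3 or 6")
        if self.effect_kind == "qaly" and not self.conversion_factor:
            raise ValueError("conversion_factor is required for QALY effects")

    def config_hash(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(self).items()
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScenarioResult:
    scenario_id: str
    effect_kind: str
    delta_cost: float
    delta_effect: float
    classification: str
    quadrants: QuadrantShares
    ceac: CeacCurve
    cloud: BootstrapCloud
    pooled: cea_engine.PooledEstimate
    seed: int
    config_hash: str
    n: int
    descriptive: bool = False

    def row(self) -> dict[str, object]:
        """Report row with costs in whole euros and shares to one decimal."""
        return {
            "scenario": self.scenario_id,
            "effect_kind": self.effect_kind,
            "incremental_cost": round(self.delta_cost),
            "incremental_effect": round(self.delta_effect, 2),
            "classification": self.classification,
            "ne": round(self.quadrants.ne, 1),
            "se": round(self.quadrants.se, 1),
            "sw": round(self.quadrants.sw, 1),
            "nw": round(self.quadrants.nw, 1),
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n": self.n,
            "descriptive": self.descriptive,
        }


def _intervention_cost_for(config: ScenarioConfig) -> float:
    return costing.intervention_cost(
        config.annual_platform_cost,
        config.annual_accounts,
        include_opportunity=config.scenario_id == "opportunity_costs",
        participant_hours=config.opportunity_hours,
        wage=config.opportunity_hourly_wage,
    )


def compute_breakdowns(
    records: Sequence[ParticipantRecord],
    prices: UnitPriceTable,
    friction: FrictionParams,
    config: ScenarioConfig,
) -> list[costing.CostBreakdown]:
    """Cost breakdowns for all observed participant-waves.

    The intervention cost lands in the 3-month breakdown of the intervention
    arm; the control arm incurs it at 6 months, after crossover.
    """
    iv = _intervention_cost_for(config)
    out = []
    for rec in records:
        for wave in WAVES:
            if rec.arm == ARM_CDMI:
                iv_wave = iv if wave == 3 else 0.0
            else:
                iv_wave = iv if wave == 6 else 0.0
            b = costing.build_cost_breakdown(
                rec, wave, prices, friction, config.ref_year, iv_wave
            )
            if b is not None:
                out.append(b)
    return out


def _impute(table: pd.DataFrame, config: ScenarioConfig) -> ImputedDatasets:
    if config.scenario_id == "regression_imputation":
        return missing_data.impute_regression(table)
    if config.scenario_id == "locf":
        return missing_data.impute_locf(table)
    return missing_data.impute_pmm(
        table,
        ImputationConfig(
            method="pmm", m=config.m, pmm_donors=config.pmm_donors, seed=config.seed
        ),
    )


def _add_effect_and_cost_columns(
    df: pd.DataFrame, config: ScenarioConfig, sd_baseline: float
) -> pd.DataFrame:
    """Derive the analysis cost total and effect column on a completed table."""
    df = df.copy()
    horizon = config.horizon_months
    waves = [3] if horizon == 3 else [3, 6]
    hc = sum(df[f"hc_m{w}"] for w in waves)
    pf = sum(df[f"pf_m{w}"] for w in waves)
    prod = sum(df[f"prod_m{w}"] for w in waves)
    # the platform account exists for every randomized participant, dropouts
    # included: the intervention cost is deterministic, never imputed, and at
    # the 6-month horizon the control arm has incurred it too (crossover)
    iv_per = _intervention_cost_for(config)
    iv = iv_per * df["arm"] if horizon == 3 else iv_per
    if config.scenario_id == "healthcare_perspective":
        df["cost_total"] = iv + hc
    else:
        df["cost_total"] = iv + hc + pf + prod
    ids_h = df[f"ids_m{horizon}"]
    df["responder"] = (
        (df["ids_m0"] - ids_h) / df["ids_m0"] >= 0.5
    ).astype(float)
    if config.effect_kind == "qaly":
        factor = config.conversion_factor
        times = [0.0] + [w / 12.0 for w in waves]
        d3 = (df["ids_m3"] - df["ids_m0"]) / sd_baseline
        u3 = np.clip(factor * -d3, -1.0, 1.0)
        if horizon == 3:
            qalys = [
                outcomes.qaly_gained([0.0, u], times, method=config.qaly_method)
                for u in u3
            ]
        else:
            d6 = (df["ids_m6"] - df["ids_m0"]) / sd_baseline
            u6 = np.clip(factor * -d6, -1.0, 1.0)
            qalys = [
                outcomes.qaly_gained([0.0, a, b], times, method=config.qaly_method)
                for a, b in zip(u3, u6)
            ]
        df["qaly"] = qalys
    return df


def _design_for(config: ScenarioConfig) -> CeaDesign:
    effect_col = "responder" if config.effect_kind == "responder_rate" else "qaly"
    if config.scenario_id == "no_baseline_adjust":
        cost_cov: tuple[str, ...] = ()
        eff_cov: tuple[str, ...] = ()
    else:
        cost_cov = ("prod_m0",)
        eff_cov = ("ids_m0",)
    return CeaDesign(
        cost_col="cost_total",
        effect_col=effect_col,
        cost_covariates=cost_cov,
        effect_covariates=eff_cov,
        effect_kind=config.effect_kind,
    )


def run_scenario(
    records: Sequence[ParticipantRecord],
    prices: UnitPriceTable,
    config: ScenarioConfig,
    friction: FrictionParams | None = None,
) -> ScenarioResult:
    """Execute one full scenario: costing, imputation, effects, bootstrapped SUR."""
    config.validate()
    friction = friction or FrictionParams()
    if config.scenario_id == "paid_job_only":
        records = [r for r in records if r.employment == "paid"]
    breakdowns = compute_breakdowns(records, prices, friction, config)
    table = missing_data.build_analysis_table(records, breakdowns)
    imputed = _impute(table, config)
    sd_baseline = float(table["ids_m0"].std(ddof=1))
    completed = [
        _add_effect_and_cost_columns(df, config, sd_baseline)
        for df in imputed.datasets
    ]
    design = _design_for(config)
    fits = [cea_engine.fit_sure_table(df, design) for df in completed]
    pooled = cea_engine.pool_point_estimates(fits)
    cloud = cea_engine.bootstrap_cloud(
        completed, design, B=config.B, seed=config.seed
    )
    quad = cea_engine.quadrant_shares(cloud)
    curve = cea_engine.ceac(cloud, config.wtp_grid)
    classification = cea_engine.icer(pooled.delta_cost, pooled.delta_effect)
    return ScenarioResult(
        scenario_id=config.scenario_id,
        effect_kind=config.effect_kind,
        delta_cost=pooled.delta_cost,
        delta_effect=pooled.delta_effect,
        classification=classification.classification,
        quadrants=quad,
        ceac=curve,
        cloud=cloud,
        pooled=pooled,
        seed=config.seed,
        config_hash=config.config_hash(),
        n=len(records),
        descriptive=config.horizon_months == 6,
    )


def run_all_scenarios(
    records: Sequence[ParticipantRecord],
    prices: UnitPriceTable,
    base_config: ScenarioConfig,
    friction: FrictionParams | None = None,
) -> list[ScenarioResult]:
    """The full sensitivity grid for one effect kind, sharing the base config."""
    results = []
    for scenario in SCENARIOS:
        cfg = replace(base_config, scenario_id=scenario)
        results.append(run_scenario(records, prices, cfg, friction))
    return results


# ---------------------------------------------------------------------------
# Design statistics


def power_two_sample_t(n_per_arm: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_arm - 2
    ncp = d * np.sqrt(n_per_arm / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def required_sample_size(
    effect_size: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Smallest per-arm n whose two-sample two-sided t-test reaches the target power.

    Uses the noncentral-t distribution with noncentrality d*sqrt(n/2) and
    2n - 2 degrees of freedom; power is monotone in n, so the search scans
    upward from a normal-approximation starting point.
    """
    if effect_size <= 0:
        raise ValueError("effect size must be positive (power unreachable at 0)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(2, int(np.floor(2.0 * ((za + zb) / effect_size) ** 2)) - 5)
    while power_two_sample_t(n, effect_size, alpha) < power:
        n += 1
    while n > 2 and power_two_sample_t(n - 1, effect_size, alpha) >= power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# Report tables


def baseline_table(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Baseline characteristics by arm (means/shares)."""
    df = missing_data.build_analysis_table(records, [])
    rows = []
    for arm, g in df.groupby("arm"):
        rows.append(
            {
                "arm": "cdmi" if arm == 1 else "control",
                "n": len(g),
                "age_mean": round(g["age"].mean(), 2),
                "female_pct": round(100 * g["sex"].mean(), 1),
                "high_education_pct": round(100 * g["education"].mean(), 1),
                "paid_employment_pct": round(100 * g["employment"].mean(), 1),
                "ids_m0_mean": round(g["ids_m0"].mean(), 2),
                "jseq0_mean": round(g["jseq0"].mean(), 2),
                "pss0_mean": round(g["pss0"].mean(), 2),
                "gad7_0_mean": round(g["gad7_0"].mean(), 2),
            }
        )
    return pd.DataFrame(rows)


def outcomes_table(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Observed (complete-case) responder rates by arm and wave, ITT denominators."""
    rows = []
    by_arm: dict[str, list[ParticipantRecord]] = {}
    for r in records:
        by_arm.setdefault(r.arm, []).append(r)
    for arm, group in sorted(by_arm.items()):
        n = len(group)
        for wave in (3, 6):
            flags = [
                outcomes.is_responder(r.ids_sr[0], r.ids_sr[wave])
                for r in group
                if r.ids_sr.get(wave) is not None and r.ids_sr.get(0)
            ]
            rows.append(
                {
                    "arm": arm,
                    "wave": wave,
                    "n_randomized": n,
                    "n_observed": len(flags),
                    "n_responders": int(sum(flags)),
                    "responder_rate_pct": outcomes.responder_rate(flags, n),
                }
            )
    return pd.DataFrame(rows)


def cost_table(
    breakdowns: Sequence[costing.CostBreakdown], wave: int
) -> pd.DataFrame:
    """Mean per-participant costs by category for one wave (whole euros)."""
    rows = []
    sub = [b for b in breakdowns if b.wave == wave]
    agg = costing.aggregate(sub, "societal")
    for col in ("intervention", "healthcare", "patient_family", "productivity", "total"):
        rows.append({"cost_type": col, "mean_eur": round(agg[col].mean())})
    return pd.DataFrame(rows)


def scenario_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])


__all__ = [
    "SCENARIOS",
    "EFFECT_KINDS",
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "run_all_scenarios",
    "compute_breakdowns",
    "power_two_sample_t",
    "required_sample_size",
    "baseline_table",
    "outcomes_table",
    "cost_table",
    "scenario_table",
]
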