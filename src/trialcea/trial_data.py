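"""Trial data model, CSV I/O, eligibility screening, and synthetic trial generation.

The data model mirrors a two-arm randomized prevention trial in adults with
mild-to-moderate depressive symptoms: a web-based complaint-directed
mini-intervention (CDMI) arm versus a waiting-list control arm, with
measurement waves at baseline, 3 and 6 months.  Depressive symptoms are
measured with the IDS-SR (Inventory of Depressive Symptomatology,
Self-Report; total score 0-84) and resource use with a cost questionnaire
covering health-care contacts, medication days, (informal) care hours and
productivity losses.

The synthetic generator emulates the statistical structure of such a trial:
baseline IDS-SR restricted to the eligibility window [14, 38], a standardized
treatment effect on the 3-month score, arm-dependent dropout driven by a
logistic model on arm, baseline anxiety (GAD-7) and age, and right-skewed
zero-inflated resource-use quantities with a baseline imbalance in
productivity losses between arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WAVES: tuple[int, ...] = (0, 3, 6)

#: Recall window of the cost questionnaire at each wave, in months.  The
#: baseline questionnaire covers the previous month; follow-up waves cover the
#: elapsed 3-month period.
WAVE_WINDOW_MONTHS: dict[int, float] = {0: 1.0, 3: 3.0, 6: 3.0}

ARM_CDMI = "cdmi"
ARM_CONTROL = "control"
ARMS = (ARM_CDMI, ARM_CONTROL)

#: Resource-use quantity fields, in CSV column order.
RESOURCE_ITEMS: tuple[str, ...] = (
    "gp_visits",
    "gp_support",
    "social_worker",
    "psychologist",
    "physiotherapist",
    "psychiatry",
    "other_visits",
    "drug_days_depression",
    "drug_days_sleep",
    "drug_days_anxiety",
    "home_care_hours",
    "special_home_care_hours",
    "informal_care_hours",
    "absenteeism_days",
    "presenteeism_days",
)

VISIT_ITEMS = RESOURCE_ITEMS[:7]
DRUG_ITEMS = RESOURCE_ITEMS[7:10]
CARE_ITEMS = RESOURCE_ITEMS[10:13]


class TrialValidationError(ValueError):
    """Base class for trial-table validation failures."""


class UnknownArmError(TrialValidationError):
    pass


class NegativeQuantityError(TrialValidationError):
    pass


class DuplicateParticipantError(TrialValidationError):
    pass


def canonical_arm(label: str) -> str:
    """Map an arm label to its canonical form, case- and space-insensitively."""
    cleaned = str(label).strip().lower()
    aliases = {
        "cdmi": ARM_CDMI,
        "intervention": ARM_CDMI,
        "control": ARM_CONTROL,
        "waiting_list": ARM_CONTROL,
        "waitlist": ARM_CONTROL,
    }
    if cleaned not in aliases:
        raise UnknownArmError(f"unknown arm label: {label!r}")
    return aliases[cleaned]


@dataclass
class ResourceUse:
    """Resource-use quantities reported for one wave's recall window.

    All quantities are non-negative; ``presenteeism_efficiency`` is the
    fraction of normal productivity achieved on presenteeism-affected days.
    """

    gp_visits: float = 0.0
    gp_support: float = 0.0
    social_worker: float = 0.0
    psychologist: float = 0.0
    physiotherapist: float = 0.0
    psychiatry: float = 0.0
    other_visits: float = 0.0
    drug_days_depression: float = 0.0
    drug_days_sleep: float = 0.0
    drug_days_anxiety: float = 0.0
    home_care_hours: float = 0.0
    special_home_care_hours: float = 0.0
    informal_care_hours: float = 0.0
    absenteeism_days: float = 0.0
    presenteeism_days: float = 0.0
    presenteeism_efficiency: float = 1.0

    def validate(self) -> None:
        for item in RESOURCE_ITEMS:
            if getattr(self, item) < 0:
                raise NegativeQuantityError(f"negative quantity for {item}")
        if not 0.0 <= self.presenteeism_efficiency <= 1.0:
            raise TrialValidationError(
                "presenteeism_efficiency must lie in [0, 1], got "
                f"{self.presenteeism_efficiency}"
            )


@dataclass
class ParticipantRecord:
    """One trial participant: arm, baseline covariates, and wave-level data.

    ``ids_sr`` maps wave (months) to IDS-SR total score; follow-up entries may
    be ``None`` (lost to follow-up).  ``resource_use`` maps wave to the
    questionnaire quantities, ``None`` when the wave was missed.
    """

    participant_id: str
    arm: str
    age: float
    sex: str  # {"F", "M"}
    education: str  # {"low", "high"}
    employment: str  # {"paid", "unpaid"}
    ids_item18: int
    jseq0: float
    pss0: float
    gad7_0: float
    ids_sr: dict[int, float | None] = field(default_factory=dict)
    resource_use: dict[int, ResourceUse | None] = field(default_factory=dict)

    def validate(self) -> None:
        self.arm = canonical_arm(self.arm)
        base = self.ids_sr.get(0)
        if base is not None and not (0 <= base <= 84):
            raise TrialValidationError(
                f"baseline IDS-SR out of [0, 84] for {self.participant_id}: {base}"
            )
        for use in self.resource_use.values():
            if use is not None:
                use.validate()


# ---------------------------------------------------------------------------
# Eligibility screening


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    rule: str


def eligibility_filter(
    records: Iterable[ParticipantRecord],
    ids_window: tuple[float, float] = (14, 38),
    item18_exclude_at: int = 2,
    min_age: float = 18,
) -> tuple[list[ParticipantRecord], list[Exclusion]]:
    """Apply the trial inclusion/exclusion rules.

    Kept records have baseline IDS-SR inside the inclusive window (default
    14-38, the indicated-prevention range for subclinical/mild depression),
    age >= ``min_age``, and a suicidality item (IDS-SR item 18) below
    ``item18_exclude_at``.  Records without a baseline IDS-SR score cannot be
    screened and are rejected with rule ``"unscreenable"``.

    Returns the kept records and a per-rule exclusion log.  Idempotent:
    filtering a filtered cohort is the identity.
    """
    lo, hi = ids_window
    kept: list[ParticipantRecord] = []
    log: list[Exclusion] = []
    for rec in records:
        base = rec.ids_sr.get(0)
        if base is None:
            log.append(Exclusion(rec.participant_id, "unscreenable"))
            continue
        rules = []
        if not lo <= base <= hi:
            rules.append("ids_out_of_window")
        if rec.age < min_age:
            rules.append("underage")
        if rec.ids_item18 >= item18_exclude_at:
            rules.append("suicidality")
        if rules:
            log.extend(Exclusion(rec.participant_id, r) for r in rules)
        else:
            kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# Synthetic trial generation


@dataclass
class SyntheticTrialConfig:
    """Configuration of the synthetic trial generator.

    Defaults are calibrated to the study conditions the pipeline targets: arms
    of 165/164, baseline IDS-SR truncated to [14, 38], a standardized 3-month
    treatment effect of d = 0.33, ~41% vs ~15% 3-month dropout driven by arm,
    baseline GAD-7 and age, ~70% paid employment, and mean baseline
    productivity losses of ~EUR 729 (intervention) vs ~EUR 582 (control) per
    month at the default daily wage.
    """

    n_per_arm: tuple[int, int] = (165, 164)  # (cdmi, control)
    baseline_ids_mean: float = 25.0
    baseline_ids_sd: float = 6.0
    treatment_effect_d: float = 0.41
    #: mean 3-month IDS-SR improvement (score points) in the control arm
    mean_change_control: float = 2.0
    change_sd: float = 7.0
    #: further mean improvement from 3 to 6 months (both arms; control has
    #: intervention access after 3 months)
    mean_change_m6: float = 2.0
    #: dropout log-odds at 3 months: intercept + arm * I(cdmi)
    #: + gad7 * (gad7_0 - 10) + age * (age - 43)
    dropout_logit_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.766,  # logit(0.146)
            "arm": 1.411,  # logit(0.412) - logit(0.146)
            "gad7_0": 0.06,
            "age": -0.015,
        }
    )
    #: additional 3->6-month dropout probability among 3-month completers,
    #: per arm (cdmi, control); yields ~59%/~50% cumulative loss
    dropout6_extra: tuple[float, float] = (0.30, 0.41)
    #: item -> (zero-inflation probability, gamma shape, gamma scale per month)
    cost_distributions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COST_DISTRIBUTIONS)
    )
    #: (p_zero, shape, scale per month) among employed, control-arm baseline
    absenteeism_dist: tuple[float, float, float] = (0.35, 3.0, 1.21)
    presenteeism_dist: tuple[float, float, float] = (0.35, 3.0, 1.62)
    #: target mean baseline productivity cost per participant, EUR, (cdmi,
    #: control); the ratio scales the cdmi arm's baseline day-count means
    productivity_baseline_means: tuple[float, float] = (729.0, 582.0)
    #: follow-up productivity day-count means relative to control baseline
    followup_productivity_factor: float = 0.85
    #: multiplier on the intervention arm's follow-up productivity day means;
    #: 1.0 keeps follow-up cost distributions arm-invariant, values < 1 encode
    #: a cost-saving treatment effect
    followup_productivity_treatment_factor: float = 1.0
    employment_rate: float = 0.70
    presenteeism_efficiency_beta: tuple[float, float] = (3.0, 2.0)  # mean 0.6
    age_mean: float = 43.0
    age_sd: float = 13.0
    female_rate: float = 0.755
    high_education_rate: float = 0.70
    jseq_mean: float = 11.4
    jseq_sd: float = 5.4
    pss_mean: float = 21.6
    pss_sd: float = 5.6
    gad7_mean: float = 10.0
    gad7_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_per_arm) <= 0:
            raise ValueError("arm sizes must be positive")
        if not 0 <= self.employment_rate <= 1:
            raise ValueError("employment_rate must lie in [0, 1]")
        for item, (p0, shape, scale) in self.cost_distributions.items():
            if not 0 <= p0 <= 1 or shape <= 0 or scale <= 0:
                raise ValueError(f"invalid cost distribution for {item}")


#: Monthly zero-inflated gamma parameters for the non-productivity items,
#: chosen to give right-skewed per-category costs of the magnitude seen in
#: primary-care depression trials under the default unit-price table.
DEFAULT_COST_DISTRIBUTIONS: dict[str, tuple[float, float, float]] = {
    "gp_visits": (0.55, 1.5, 1.3),
    "gp_support": (0.90, 1.0, 1.2),
    "social_worker": (0.95, 1.0, 1.5),
    "psychologist": (0.85, 1.2, 1.5),
    "physiotherapist": (0.85, 1.5, 2.2),
    "psychiatry": (0.93, 1.0, 3.5),
    "other_visits": (0.88, 1.0, 2.4),
    "drug_days_depression": (0.60, 2.0, 14.0),
    "drug_days_sleep": (0.70, 2.0, 12.0),
    "drug_days_anxiety": (0.75, 2.0, 12.0),
    "home_care_hours": (0.95, 1.0, 2.0),
    "special_home_care_hours": (0.97, 1.0, 2.0),
    "informal_care_hours": (0.70, 1.2, 6.0),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _truncnorm_scores(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    # inverse-CDF truncated normal, rounded to integer scores inside the window
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    x = stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)
    return np.clip(np.round(x), lo, hi)


def _zig(
    rng: np.random.Generator,
    n: int,
    p_zero: float,
    shape: float,
    scale: float,
    window: float,
) -> np.ndarray:
    """Zero-inflated gamma draw with mean scaling by the recall window."""
    active = rng.uniform(size=n) >= p_zero
    out = np.zeros(n)
    k = int(active.sum())
    if k:
        out[active] = rng.gamma(shape, scale * window, size=k)
    return out


def generate_trial(config: SyntheticTrialConfig | None = None) -> list[ParticipantRecord]:
    """Generate a synthetic two-arm trial cohort.

    Reproducible given ``config.seed``; arm sizes are exactly as configured.
    Follow-up IDS-SR scores are clamped to [0, 84] (a warning reports the
    clamp count when nonzero).  Dropout is monotone: a participant missing at
    3 months is also missing at 6 months, and a missed wave removes both the
    symptom score and the resource-use questionnaire for that wave.
    """
    cfg = config or SyntheticTrialConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_cdmi, n_control = cfg.n_per_arm
    n = n_cdmi + n_control
    arm = np.zeros(n, dtype=int)
    arm[:n_cdmi] = 1  # 1 = cdmi

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 85)
    female = rng.uniform(size=n) < cfg.female_rate
    high_edu = rng.uniform(size=n) < cfg.high_education_rate
    paid = rng.uniform(size=n) < cfg.employment_rate
    jseq0 = np.clip(rng.normal(cfg.jseq_mean, cfg.jseq_sd, n), 0, 24).round(1)
    pss0 = np.clip(rng.normal(cfg.pss_mean, cfg.pss_sd, n), 0, 40).round(1)
    gad7 = np.clip(np.round(rng.normal(cfg.gad7_mean, cfg.gad7_sd, n)), 0, 21)
    item18 = (rng.uniform(size=n) < 0.25).astype(int)  # 0 or 1; eligible by design

    ids0 = _truncnorm_scores(
        rng, n, cfg.baseline_ids_mean, cfg.baseline_ids_sd, 14, 38
    )

    # 3-month change: control improves by mean_change_control on average; the
    # intervention adds d * baseline SD on top.
    shift = cfg.mean_change_control + cfg.treatment_effect_d * cfg.baseline_ids_sd * arm
    ids3_raw = ids0 - shift + rng.normal(0, cfg.change_sd, n)
    ids6_raw = ids3_raw - cfg.mean_change_m6 + rng.normal(0, cfg.change_sd, n)
    n_clamped = int(((ids3_raw < 0) | (ids3_raw > 84)).sum())
    n_clamped += int(((ids6_raw < 0) | (ids6_raw > 84)).sum())
    ids3 = np.clip(np.round(ids3_raw), 0, 84)
    ids6 = np.clip(np.round(ids6_raw), 0, 84)
    if n_clamped:
        warnings.warn(
            f"{n_clamped} follow-up IDS-SR draws clamped to [0, 84]",
            stacklevel=2,
        )

    c = cfg.dropout_logit_coefs
    p_drop3 = _sigmoid(
        c["intercept"]
        + c["arm"] * arm
        + c["gad7_0"] * (gad7 - 10.0)
        + c["age"] * (age - 43.0)
    )
    drop3 = rng.uniform(size=n) < p_drop3
    extra6 = np.where(arm == 1, cfg.dropout6_extra[0], cfg.dropout6_extra[1])
    drop6 = drop3 | (rng.uniform(size=n) < extra6)

    prod_scale = cfg.productivity_baseline_means[0] / cfg.productivity_baseline_means[1]
    eff_a, eff_b = cfg.presenteeism_efficiency_beta

    # vectorized per-wave resource-use draws; dropout masking happens below
    wave_use: dict[int, dict[str, np.ndarray]] = {}
    for wave in WAVES:
        window = WAVE_WINDOW_MONTHS[wave]
        vals: dict[str, np.ndarray] = {}
        for item, (p0, shape, scale) in cfg.cost_distributions.items():
            q = _zig(rng, n, p0, shape, scale, window)
            vals[item] = np.round(q) if item in VISIT_ITEMS + DRUG_ITEMS else np.round(q, 1)
        if wave == 0:
            mult = np.where(arm == 1, prod_scale, 1.0)
        else:
            mult = cfg.followup_productivity_factor * np.where(
                arm == 1, cfg.followup_productivity_treatment_factor, 1.0
            )
        p0a, ka, sa = cfg.absenteeism_dist
        p0p, kp, sp = cfg.presenteeism_dist
        vals["absenteeism_days"] = np.round(
            paid * mult * _zig(rng, n, p0a, ka, sa, window), 1
        )
        vals["presenteeism_days"] = np.round(
            paid * mult * _zig(rng, n, p0p, kp, sp, window), 1
        )
        vals["presenteeism_efficiency"] = np.round(rng.beta(eff_a, eff_b, size=n), 2)
        wave_use[wave] = vals

    records: list[ParticipantRecord] = []
    width = len(str(n))
    for i in range(n):
        use: dict[int, ResourceUse | None] = {}
        for wave in WAVES:
            if (wave == 3 and drop3[i]) or (wave == 6 and drop6[i]):
                use[wave] = None
                continue
            use[wave] = ResourceUse(
                **{k: float(v[i]) for k, v in wave_use[wave].items()}
            )

        ids_map: dict[int, float | None] = {
            0: float(ids0[i]),
            3: None if drop3[i] else float(ids3[i]),
            6: None if drop6[i] else float(ids6[i]),
        }
        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:0{width}d}",
                arm=ARM_CDMI if arm[i] == 1 else ARM_CONTROL,
                age=float(np.round(age[i], 1)),
                sex="F" if female[i] else "M",
                education="high" if high_edu[i] else "low",
                employment="paid" if paid[i] else "unpaid",
                ids_item18=int(item18[i]),
                jseq0=float(jseq0[i]),
                pss0=float(pss0[i]),
                gad7_0=float(gad7[i]),
                ids_sr=ids_map,
                resource_use=use,
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV I/O

_BASE_COLUMNS = (
    "participant_id",
    "arm",
    "age",
    "sex",
    "education",
    "employment",
    "ids_item18",
    "jseq0",
    "pss0",
    "gad7_0",
)


def _resource_columns() -> list[str]:
    cols = []
    for wave in WAVES:
        for item in (*RESOURCE_ITEMS, "presenteeism_efficiency"):
            cols.append(f"{item}_m{wave}")
    return cols


def trial_columns() -> list[str]:
    return (
        list(_BASE_COLUMNS)
        + [f"ids_sr_m{w}" for w in WAVES]
        + _resource_columns()
    )


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "participant_id": rec.participant_id,
            "arm": rec.arm,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
            "employment": rec.employment,
            "ids_item18": rec.ids_item18,
            "jseq0": rec.jseq0,
            "pss0": rec.pss0,
            "gad7_0": rec.gad7_0,
        }
        for w in WAVES:
            row[f"ids_sr_m{w}"] = rec.ids_sr.get(w)
        for w in WAVES:
            use = rec.resource_use.get(w)
            for item in (*RESOURCE_ITEMS, "presenteeism_efficiency"):
                row[f"{item}_m{w}"] = None if use is None else getattr(use, item)
        rows.append(row)
    return pd.DataFrame(rows, columns=trial_columns())


def write_trial_csv(records: Sequence[ParticipantRecord], path) -> None:
    """Write the trial table; missing values become empty cells."""
    records_to_frame(records).to_csv(path, index=False)


def read_trial_csv(path) -> list[ParticipantRecord]:
    """Read a trial table, validating arms, signs, and participant uniqueness.

    A wave whose resource-use cells are all empty is treated as a missed wave
    (``resource_use[wave] is None``); otherwise empty cells within the wave
    default to zero quantities.
    """
    df = pd.read_csv(path)
    missing_cols = set(_BASE_COLUMNS) | {f"ids_sr_m{w}" for w in WAVES}
    missing_cols -= set(df.columns)
    if missing_cols:
        raise TrialValidationError(f"missing columns: {sorted(missing_cols)}")
    dupes = df["participant_id"].astype(str)[df["participant_id"].duplicated()]
    if len(dupes):
        raise DuplicateParticipantError(
            f"duplicated participant_id: {sorted(dupes.unique())}"
        )
    records = []
    for idx, row in df.iterrows():
        arm = canonical_arm(row["arm"])
        ids_map: dict[int, float | None] = {}
        for w in WAVES:
            v = row.get(f"ids_sr_m{w}")
            ids_map[w] = None if pd.isna(v) else float(v)
        use_map: dict[int, ResourceUse | None] = {}
        for w in WAVES:
            cols = [f"{item}_m{w}" for item in (*RESOURCE_ITEMS, "presenteeism_efficiency")]
            present = [c for c in cols if c in df.columns]
            vals = {c: row[c] for c in present}
            if not present or all(pd.isna(v) for v in vals.values()):
                use_map[w] = None
                continue
            kwargs = {}
            for item in RESOURCE_ITEMS:
                col = f"{item}_m{w}"
                v = row.get(col)
                q = 0.0 if pd.isna(v) else float(v)
                if q < 0:
                    raise NegativeQuantityError(
                        f"negative quantity at row {idx}, column {col}: {q}"
                    )
                kwargs[item] = q
            eff = row.get(f"presenteeism_efficiency_m{w}")
            kwargs["presenteeism_efficiency"] = 1.0 if pd.isna(eff) else float(eff)
            use_map[w] = ResourceUse(**kwargs)
        rec = ParticipantRecord(
            participant_id=str(row["participant_id"]),
            arm=arm,
            age=float(row["age"]),
            sex=str(row["sex"]).strip().upper(),
            education=str(row["education"]).strip().lower(),
            employment=str(row["employment"]).strip().lower(),
            ids_item18=int(row["ids_item18"]),
            jseq0=float(row["jseq0"]),
            pss0=float(row["pss0"]),
            gad7_0=float(row["gad7_0"]),
            ids_sr=ids_map,
            resource_use=use_map,
        )
        rec.validate()
        records.append(rec)
    return records


__all__ = [
    "WAVES",
    "WAVE_WINDOW_MONTHS",
    "ARM_CDMI",
    "ARM_CONTROL",
    "RESOURCE_ITEMS",
    "VISIT_ITEMS",
    "DRUG_ITEMS",
    "CARE_ITEMS",
    "ResourceUse",
    "ParticipantRecord",
    "SyntheticTrialConfig",
    "Exclusion",
    "TrialValidationError",
    "UnknownArmError",
    "NegativeQuantityError",
    "DuplicateParticipantError",
    "canonical_arm",
    "eligibility_filter",
    "generate_trial",
    "records_to_frame",
    "read_trial_csv",
    "write_trial_csv",
    "trial_columns",
]
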