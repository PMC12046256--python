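"""Seeded generator of a synthetic pre-anesthesia cohort.

The study cohort this package targets (patients screened by a digital
pre-anesthesia questionnaire) is not publicly deposited, so every other
module is exercised against this synthetic stand-in: 85 mixed-type clinical
features — 19 numerical, 60 binary comorbidity/medication flags, 6
four-level categoricals — which encode to a 103-column design matrix.

Records are drawn from a latent-factor model: k standard-normal factors per
patient (broadly: frailty/age, cardiometabolic burden, respiratory burden,
lifestyle) drive correlated numerics, prevalence-calibrated binaries via a
logistic link, and categoricals via softmax scores.  The factor structure
gives the correlation-stability audit real signal to preserve.  Ranges and
prevalences are clinically plausible inventions; they make no claim of
matching any real cohort's marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import ColumnSpec, CohortSchema, CohortTable

K_FACTORS = 4

# (name, min, max, integer, mean, sd, loadings on the 4 factors)
_NUMERIC_DEFS: list[tuple[str, float, float, bool, float, float, tuple]] = [
    ("age_years", 18, 95, True, 54, 16, (0.85, 0.1, 0.0, 0.0)),
    ("weight_kg", 40, 160, False, 78, 16, (0.0, 0.8, 0.0, 0.1)),
    ("height_cm", 140, 210, False, 170, 9, (-0.1, 0.3, 0.0, 0.0)),
    # BMI is overwritten below: derived exactly from weight/height
    ("bmi", 8, 85, False, 27, 5, (0.0, 0.7, 0.0, 0.0)),
    ("systolic_bp_mmhg", 80, 220, True, 132, 18, (0.4, 0.55, 0.0, 0.1)),
    ("diastolic_bp_mmhg", 40, 130, True, 79, 11, (0.2, 0.55, 0.0, 0.1)),
    ("heart_rate_bpm", 40, 160, True, 76, 13, (0.0, 0.3, 0.35, 0.2)),
    ("respiratory_rate", 8, 40, True, 16, 3, (0.1, 0.0, 0.7, 0.0)),
    ("spo2_percent", 80, 100, True, 97, 2, (-0.2, -0.1, -0.75, 0.0)),
    # hb and hct share a 0.9 loading: they are near-duplicate measurements
    ("hemoglobin_g_dl", 6, 20, False, 13.8, 1.6, (-0.3, 0.1, 0.9, 0.0)),
    ("hematocrit_percent", 20, 60, False, 41, 4.5, (-0.3, 0.1, 0.9, 0.0)),
    ("platelets_g_l", 50, 600, True, 260, 70, (-0.2, 0.1, 0.0, 0.0)),
    ("creatinine_umol_l", 30, 400, True, 80, 25, (0.5, 0.3, 0.0, 0.0)),
    ("glucose_mmol_l", 3, 25, False, 5.9, 1.6, (0.3, 0.6, 0.0, 0.0)),
    ("albumin_g_l", 20, 55, False, 41, 4, (-0.6, -0.1, -0.1, 0.0)),
    ("alt_u_l", 5, 300, True, 28, 14, (0.1, 0.4, 0.0, 0.3)),
    ("sodium_mmol_l", 120, 155, True, 140, 3, (-0.2, 0.0, 0.0, 0.0)),
    ("potassium_mmol_l", 2.5, 7.0, False, 4.2, 0.4, (0.3, 0.1, 0.0, 0.0)),
    ("crp_mg_l", 0, 200, False, 8, 9, (0.35, 0.2, 0.4, 0.0)),
]

# 60 binary flags: (name, base prevalence, loadings)
_BINARY_DEFS: list[tuple[str, float, tuple]] = [
    ("hypertension", 0.35, (1.2, 0.9, 0.0, 0.2)),
    ("diabetes_type2", 0.15, (0.8, 1.2, 0.0, 0.2)),
    ("current_smoker", 0.25, (-0.3, 0.0, 0.6, 1.1)),
    ("former_smoker", 0.22, (0.6, 0.1, 0.4, 0.8)),
    ("asthma", 0.09, (-0.2, 0.1, 1.2, 0.0)),
    ("copd", 0.07, (0.7, 0.1, 1.4, 0.4)),
    ("sleep_apnea", 0.10, (0.3, 1.1, 0.6, 0.1)),
    ("coronary_artery_disease", 0.10, (1.1, 0.8, 0.1, 0.3)),
    ("heart_failure", 0.05, (1.2, 0.7, 0.4, 0.1)),
    ("atrial_fibrillation", 0.08, (1.3, 0.4, 0.1, 0.1)),
    ("stroke_history", 0.05, (1.1, 0.5, 0.0, 0.2)),
    ("peripheral_artery_disease", 0.06, (0.9, 0.6, 0.1, 0.6)),
    ("chronic_kidney_disease", 0.07, (1.0, 0.7, 0.0, 0.0)),
    ("liver_disease", 0.04, (0.4, 0.4, 0.0, 0.8)),
    ("hypothyroidism", 0.09, (0.5, 0.3, 0.0, -0.2)),
    ("cancer_history", 0.12, (0.9, 0.1, 0.2, 0.2)),
    ("anemia", 0.08, (0.7, 0.0, 0.1, 0.0)),
    ("gerd", 0.14, (0.2, 0.6, 0.1, 0.2)),
    ("hiatal_hernia", 0.06, (0.5, 0.4, 0.0, 0.0)),
    ("osteoporosis", 0.07, (1.2, -0.2, 0.0, 0.0)),
    ("rheumatoid_arthritis", 0.04, (0.7, 0.1, 0.1, 0.0)),
    ("osteoarthritis", 0.18, (1.1, 0.5, 0.0, 0.0)),
    ("depression", 0.13, (0.1, 0.2, 0.1, 0.6)),
    ("anxiety_disorder", 0.15, (-0.2, 0.1, 0.2, 0.5)),
    ("epilepsy", 0.03, (0.1, 0.0, 0.0, 0.3)),
    ("migraine", 0.10, (-0.4, 0.0, 0.0, 0.2)),
    ("glaucoma", 0.05, (0.9, 0.1, 0.0, 0.0)),
    ("dvt_history", 0.05, (0.6, 0.5, 0.1, 0.2)),
    ("pulmonary_embolism_history", 0.03, (0.6, 0.5, 0.3, 0.1)),
    ("bleeding_disorder", 0.03, (0.2, 0.0, 0.0, 0.1)),
    ("allergy_antibiotics", 0.11, (0.1, 0.1, 0.1, 0.0)),
    ("allergy_latex", 0.03, (0.0, 0.1, 0.1, 0.0)),
    ("allergy_nsaid", 0.05, (0.1, 0.1, 0.0, 0.0)),
    ("difficult_intubation_history", 0.04, (0.2, 0.6, 0.3, 0.0)),
    ("ponv_history", 0.12, (-0.3, 0.1, 0.0, 0.1)),
    ("motion_sickness", 0.10, (-0.3, 0.0, 0.0, 0.1)),
    ("prior_general_anesthesia", 0.45, (0.5, 0.2, 0.1, 0.1)),
    ("anesthesia_complication_history", 0.04, (0.3, 0.2, 0.2, 0.1)),
    ("family_anesthesia_complication", 0.02, (0.0, 0.0, 0.1, 0.0)),
    ("dental_prosthesis", 0.14, (1.0, 0.2, 0.1, 0.2)),
    ("loose_teeth", 0.05, (0.6, 0.0, 0.1, 0.5)),
    ("med_antihypertensive", 0.32, (1.2, 0.9, 0.0, 0.1)),
    ("med_beta_blocker", 0.14, (1.1, 0.6, 0.0, 0.1)),
    ("med_statin", 0.22, (1.1, 0.9, 0.0, 0.1)),
    ("med_antiplatelet", 0.12, (1.1, 0.6, 0.1, 0.2)),
    ("med_anticoagulant", 0.07, (1.2, 0.4, 0.1, 0.1)),
    ("med_antidiabetic", 0.13, (0.8, 1.2, 0.0, 0.1)),
    ("med_insulin", 0.04, (0.7, 1.0, 0.0, 0.1)),
    ("med_diuretic", 0.10, (1.1, 0.7, 0.1, 0.0)),
    ("med_ppi", 0.16, (0.5, 0.5, 0.1, 0.2)),
    ("med_antidepressant", 0.11, (0.2, 0.2, 0.1, 0.5)),
    ("med_anxiolytic", 0.09, (0.3, 0.1, 0.1, 0.4)),
    ("med_opioid", 0.06, (0.4, 0.3, 0.1, 0.4)),
    ("med_corticosteroid", 0.05, (0.4, 0.1, 0.6, 0.1)),
    ("med_bronchodilator", 0.08, (0.2, 0.1, 1.3, 0.2)),
    ("med_thyroid_hormone", 0.08, (0.5, 0.2, 0.0, -0.1)),
    ("med_nsaid_regular", 0.08, (0.1, 0.2, 0.0, 0.2)),
    ("pacemaker", 0.02, (1.2, 0.3, 0.1, 0.0)),
    ("home_oxygen", 0.02, (0.8, 0.2, 1.5, 0.2)),
    ("mobility_aid", 0.06, (1.4, 0.3, 0.3, 0.0)),
]

# 6 categoricals, 4 ordered levels each: (name, levels, per-level factor score rows)
_CATEGORICAL_DEFS: list[tuple[str, tuple, np.ndarray]] = [
    (
        "met_class",
        ("lt4", "4to6", "6to10", "gt10"),
        np.array(
            [
                [1.2, 0.6, 0.8, 0.1],
                [0.4, 0.2, 0.2, 0.0],
                [-0.4, -0.2, -0.4, 0.0],
                [-1.2, -0.6, -0.8, -0.1],
            ]
        ),
    ),
    (
        "asa_class",
        ("I", "II", "III", "IV"),
        np.array(
            [
                [-1.4, -0.8, -0.6, -0.2],
                [-0.1, 0.0, -0.1, 0.0],
                [1.0, 0.7, 0.6, 0.2],
                [1.9, 1.2, 1.2, 0.3],
            ]
        ),
    ),
    (
        "anesthesia_type",
        ("general", "regional", "sedation", "combined"),
        np.array(
            [
                [0.0, 0.1, 0.0, 0.1],
                [0.4, 0.1, 0.3, -0.1],
                [-0.3, -0.1, 0.1, 0.0],
                [0.2, 0.2, 0.1, 0.1],
            ]
        ),
    ),
    (
        "alcohol_use",
        ("none", "occasional", "moderate", "heavy"),
        np.array(
            [
                [0.3, -0.1, 0.0, -1.0],
                [-0.2, 0.0, 0.0, 0.0],
                [-0.1, 0.1, 0.1, 0.7],
                [0.0, 0.2, 0.3, 1.6],
            ]
        ),
    ),
    (
        "mallampati_class",
        ("I", "II", "III", "IV"),
        np.array(
            [
                [-0.8, -0.8, -0.3, -0.1],
                [0.0, 0.0, 0.0, 0.0],
                [0.5, 0.7, 0.3, 0.1],
                [1.0, 1.3, 0.6, 0.2],
            ]
        ),
    ),
    (
        "functional_status",
        ("independent", "partially_dependent", "dependent", "bedridden"),
        np.array(
            [
                [-1.0, -0.3, -0.5, -0.1],
                [0.8, 0.2, 0.4, 0.1],
                [1.6, 0.5, 0.9, 0.2],
                [2.4, 0.7, 1.4, 0.3],
            ]
        ),
    ),
]


def fixture_schema() -> CohortSchema:
    """The fixed 85-feature layout (encoded width 103)."""
    cols: list[ColumnSpec] = []
    for name, lo, hi, integer, _, _, _ in _NUMERIC_DEFS:
        cols.append(
            ColumnSpec(
                name=name, kind="numerical", min=float(lo), max=float(hi),
                integer_valued=integer,
            )
        )
    for name, _, _ in _BINARY_DEFS:
        cols.append(ColumnSpec(name=name, kind="binary", levels=("no", "yes")))
    for name, levels, _ in _CATEGORICAL_DEFS:
        cols.append(ColumnSpec(name=name, kind="categorical", levels=levels))
    return CohortSchema(tuple(cols))


@dataclass
class FixtureConfig:
    """Parameters of the synthetic cohort's generative law.

    Defaults mirror the study setting: 521 patients, 85 features, 4 latent
    factors.  ``factor_scale`` multiplies the categorical/binary factor
    loadings; ``numeric_noise`` is the residual sd left after the factor
    contribution (loadings are correlation-scaled: a numeric with loading
    vector w has residual sd sqrt(1-||w||^2) so its marginal stays unit-sd
    before the affine map to clinical units).
    """

    n_patients: int = 521
    seed: int = 20210521
    latent_factors: int = K_FACTORS
    factor_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.latent_factors != K_FACTORS:
            raise ValueError(f"fixture uses a fixed {K_FACTORS}-factor law")


def generate_fixture(config: FixtureConfig | None = None) -> CohortTable:
    """Draw a seeded synthetic cohort from the latent-factor law."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    schema = fixture_schema()
    f = rng.standard_normal((n, K_FACTORS))

    cols: dict[str, np.ndarray] = {}
    for name, lo, hi, integer, mu, sd, w in _NUMERIC_DEFS:
        w = np.asarray(w, dtype=float)
        resid = np.sqrt(max(1.0 - float(w @ w), 0.05))
        z = f @ w + resid * rng.standard_normal(n)
        vals = np.clip(mu + sd * z, lo, hi)
        if integer:
            vals = np.round(vals)
        else:
            vals = np.round(vals, 1)
        cols[name] = vals
    # BMI derived exactly from weight and height (then bounded by its spec)
    h_m = cols["height_cm"] / 100.0
    cols["bmi"] = np.round(cols["weight_kg"] / h_m**2, 1)

    for name, prev, w in _BINARY_DEFS:
        w = config.factor_scale * np.asarray(w, dtype=float)
        logit = np.log(prev / (1 - prev)) + f @ w
        p = 1.0 / (1.0 + np.exp(-logit))
        draw = rng.random(n) < p
        cols[name] = np.where(draw, "yes", "no").astype(object)

    for name, levels, scores in _CATEGORICAL_DEFS:
        s = config.factor_scale * (f @ scores.T)  # n x 4 level scores
        s = s - s.max(axis=1, keepdims=True)
        p = np.exp(s)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        idx = (p.cumsum(axis=1) < u).sum(axis=1)
        cols[name] = np.array(levels, dtype=object)[idx]

    df = pd.DataFrame(cols, columns=schema.names)
    return CohortTable(schema=schema, data=df)


def resample_fixture(config: FixtureConfig, n: int, seed: int) -> CohortTable:
    """Fresh draw of ``n`` patients from the same generative law.

    Used as the same-distribution oracle when calibrating the fidelity
    components: a resample should score high on every component.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = FixtureConfig(
        n_patients=n,
        seed=seed,
        latent_factors=config.latent_factors,
        factor_scale=config.factor_scale,
    )
    return generate_fixture(cfg)
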