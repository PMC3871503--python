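"""Synthetic cohort generation for the femoral-PAD treatment task.

The real study cohort (186 single-hospital records, 114 men aged 53 +/- 7 and
72 women aged 58 +/- 5, 89 medical vs 97 surgical decisions) is private, so
every downstream stage is exercised on synthetic cohorts that reproduce that
demographic skeleton: exact class and sex counts, sex-specific age normals,
and class-conditional clinical features with a single tunable separation
knob.

Separation model.  The medical class draws each categorical feature from a
baseline distribution covering every category with nonzero mass.  For the
operation class, category k of a feature with top category k_max has its
probability re-weighted by ``exp(tilt_scale * class_effect * k / k_max)``
and renormalised (categories are indexed in order of increasing clinical
severity) -- an exponential-family tilt that leaves both supports identical
and makes ``class_effect = 0`` an exact null (labels carry no signal).  The
exponential form is needed because the published feature encoding is fixed:
a merely linear re-weighting cannot shift the bounded ordinal codes far
enough for the two classes ever to become strongly separable, whereas real
surgical cohorts concentrate heavily in the severe categories.  The embolism
percentage is Beta-distributed on [0, 100] with the operation class's Beta
parameters shifted upward by the same knob.  Baseline marginals are a
structural choice, not an epidemiological claim: the source study reports no
feature marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np

from .clinical_data import (
    MEDICAL,
    OPERATION,
    PatientRecord,
)
from .errors import CohortSpecError

# Category labels per tilted feature, ordered by increasing severity; the
# operation-class tilt pushes mass toward the right end of each list.
_CATEGORICAL_LEVELS = {
    "fontaine_stage": ["I", "II-a", "II-b", "III", "IV"],
    "lesion_type": ["A", "B", "C", "D"],
    "anesthesia_sensitivity": ["low", "medium-high"],
    "distal_bed": ["absent", "present"],
    "ldl_category": [0, 1, 2, 3, 4],
    "smoking": ["absent", "present"],
    "exsmoker": ["absent", "present"],
    "hypertension": ["absent", "present"],
    "blood_pressure_category": [0, 1, 2, 3],
    "diabetes": ["absent", "present"],
    "other_pad_history": ["absent", "present"],
    "family_history": ["absent", "present"],
    "current_treatment": ["absent", "present"],
}

# Medical-class baseline marginals.  Every category has nonzero probability
# so both classes share full support whatever the tilt.
_BASELINE_PROBS = {
    "fontaine_stage": (0.25, 0.25, 0.20, 0.18, 0.12),
    "lesion_type": (0.30, 0.30, 0.25, 0.15),
    "anesthesia_sensitivity": (0.60, 0.40),
    "distal_bed": (0.65, 0.35),
    "ldl_category": (0.25, 0.25, 0.20, 0.20, 0.10),
    "smoking": (0.55, 0.45),
    "exsmoker": (0.75, 0.25),
    "hypertension": (0.55, 0.45),
    "blood_pressure_category": (0.30, 0.30, 0.25, 0.15),
    "diabetes": (0.70, 0.30),
    "other_pad_history": (0.80, 0.20),
    "family_history": (0.70, 0.30),
    "current_treatment": (0.60, 0.40),
}

# Embolism % / 100 ~ Beta(a, b); the operation class concentrates higher.
_EMBOLISM_MEDICAL = (2.0, 6.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    ``class_effect`` may be a single float in [0, 1] applied to every tilted
    feature, or a mapping from feature name to a per-feature value.
    """

    n_total: int = 186
    n_medical: int = 89
    n_operation: int = 97
    n_male: int = 114
    male_age_mean: float = 53.0
    male_age_sd: float = 7.0
    female_age_mean: float = 58.0
    female_age_sd: float = 5.0
    class_effect: Union[float, Mapping[str, float]] = 0.5
    tilt_scale: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_medical + self.n_operation != self.n_total:
            raise CohortSpecError(
                f"class counts {self.n_medical}+{self.n_operation} != {self.n_total}"
            )
        if not 0 <= self.n_male <= self.n_total:
            raise CohortSpecError(f"n_male {self.n_male} out of [0, {self.n_total}]")
        if self.n_total <= 0:
            raise CohortSpecError("n_total must be positive")
        for sd in (self.male_age_sd, self.female_age_sd):
            if not sd > 0:
                raise CohortSpecError(f"age SD must be > 0, got {sd}")
        if self.tilt_scale < 0:
            raise CohortSpecError(f"tilt_scale must be >= 0, got {self.tilt_scale}")
        for name, value in self._effects().items():
            if not 0.0 <= value <= 1.0:
                raise CohortSpecError(
                    f"class_effect[{name}] = {value} out of [0, 1]"
                )

    def _effects(self) -> dict:
        names = [*_CATEGORICAL_LEVELS, "embolism"]
        if isinstance(self.class_effect, Mapping):
            unknown = set(self.class_effect) - set(names)
            if unknown:
                raise CohortSpecError(f"unknown class_effect features: {unknown}")
            return {n: float(self.class_effect.get(n, 0.0)) for n in names}
        return {n: float(self.class_effect) for n in names}


def default_spec(**overrides) -> CohortSpec:
    """The study-cohort skeleton: 186 patients, 89 medical / 97 operation,
    114 men aged ~N(53, 7), 72 women aged ~N(58, 5), moderate separation."""
    spec = CohortSpec(**overrides) if overrides else CohortSpec()
    spec.validate()
    return spec


def _tilted(probs, effect: float, scale: float) -> np.ndarray:
    """Severity tilt: re-weight category k by exp(scale * effect * k / k_max)."""
    p = np.asarray(probs, dtype=float)
    k_max = len(p) - 1
    w = p * np.exp(scale * effect * np.arange(len(p)) / k_max)
    return w / w.sum()


def _truncated_normal_ages(rng, n, mean, sd, lo=18.0, hi=100.0) -> np.ndarray:
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw > lo) & (draw < hi)]
        take = min(len(draw), n - filled)
        ages[filled:filled + take] = draw[:take]
        filled += take
    return np.rint(ages).astype(int)


def generate(spec: CohortSpec) -> list[PatientRecord]:
    """Draw one labeled cohort; a pure function of the spec (seed included).

    Class and sex counts are exact; sex is assigned independently of class by
    a seeded shuffle.  Ages are truncated-normal in (18, 100), rounded to
    integer years.  Categorical features follow the class-conditional tilt
    described in the module docstring; embolism is Beta on [0, 100], rounded
    to 0.1 %.
    """
    spec.validate()
    effects = spec._effects()
    rng = np.random.default_rng(spec.seed)

    decisions = np.array(
        [MEDICAL] * spec.n_medical + [OPERATION] * spec.n_operation
    )
    sexes = np.array(
        ["male"] * spec.n_male + ["female"] * (spec.n_total - spec.n_male)
    )
    rng.shuffle(sexes)

    n_male = int(np.sum(sexes == "male"))
    male_ages = _truncated_normal_ages(
        rng, n_male, spec.male_age_mean, spec.male_age_sd
    )
    female_ages = _truncated_normal_ages(
        rng, spec.n_total - n_male, spec.female_age_mean, spec.female_age_sd
    )
    ages = np.empty(spec.n_total, dtype=int)
    ages[sexes == "male"] = male_ages
    ages[sexes == "female"] = female_ages

    # Class-conditional categorical draws, one vectorised draw per feature.
    feature_values: dict[str, np.ndarray] = {}
    is_op = decisions == OPERATION
    for name, levels in _CATEGORICAL_LEVELS.items():
        base = np.asarray(_BASELINE_PROBS[name])
        tilt = _tilted(base, effects[name], spec.tilt_scale)
        idx = np.where(
            is_op,
            rng.choice(len(levels), size=spec.n_total, p=tilt),
            rng.choice(len(levels), size=spec.n_total, p=base),
        )
        feature_values[name] = np.asarray(levels, dtype=object)[idx]

    a0, b0 = _EMBOLISM_MEDICAL
    e = effects["embolism"]
    a_op, b_op = a0 + 6.0 * e, b0 - 3.0 * e
    emb = np.where(
        is_op,
        rng.beta(a_op, b_op, size=spec.n_total),
        rng.beta(a0, b0, size=spec.n_total),
    )
    emb = np.round(100.0 * emb, 1)

    records = []
    for i in range(spec.n_total):
        rec = PatientRecord(
            age=int(ages[i]),
            sex=str(sexes[i]),
            fontaine_stage=str(feature_values["fontaine_stage"][i]),
            lesion_type=str(feature_values["lesion_type"][i]),
            anesthesia_sensitivity=str(feature_values["anesthesia_sensitivity"][i]),
            distal_bed=str(feature_values["distal_bed"][i]),
            embolism=float(emb[i]),
            ldl_category=int(feature_values["ldl_category"][i]),
            smoking=str(feature_values["smoking"][i]),
            exsmoker=str(feature_values["exsmoker"][i]),
            hypertension=str(feature_values["hypertension"][i]),
            blood_pressure_category=int(feature_values["blood_pressure_category"][i]),
            diabetes=str(feature_values["diabetes"][i]),
            other_pad_history=str(feature_values["other_pad_history"][i]),
            family_history=str(feature_values["family_history"][i]),
            current_treatment=str(feature_values["current_treatment"][i]),
            decision=str(decisions[i]),
        )
        rec.validate()
        records.append(rec)
    return records
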