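"""Patient-record schema, clinical feature encoding, and cohort file I/O.

Each femoral peripheral-arterial-disease patient is described by 16 clinical
features (demographics, Fontaine symptom stage, TASC II lesion type,
comorbidities and risk factors) plus a binary treatment decision: medical
management versus surgical/endovascular revascularisation.  The encoders map
raw clinical values onto the fixed numeric code table used by the network:
age and embolism percentage are rescaled to [0, 1.3] / [0, 1], ordered
clinical scales (Fontaine stage, TASC type, LDL category, blood-pressure
category) become small ordinal codes, and binary findings become 0/1.
The treatment decision is coded medical = -1, operation = +1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

MEDICAL, OPERATION = "medical", "operation"
LABEL_CODES = {MEDICAL: -1, OPERATION: 1}

# Ordinal code tables.  The Fontaine and lesion maps are kept as module-level
# constants because the published code table assigns stage I and II-a the same
# code (0, skipping 1) and skips 2 for TASC type C; callers who believe those
# are transcription slips can rebind the maps before encoding.
FONTAINE_CODES = {"I": 0, "II-a": 0, "II-b": 2, "III": 3, "IV": 4}
LESION_CODES = {"A": 0, "B": 1, "C": 3, "D": 4}

SEX_CODES = {"female": 0, "male": 1}
ANESTHESIA_CODES = {"low": 0, "medium-high": 1}
BINARY_CODES = {"absent": 0, "present": 1}

#: Feature slots in code-table row order; also the CSV column order.
FEATURE_NAMES = (
    "age",
    "sex",
    "fontaine_stage",
    "lesion_type",
    "anesthesia_sensitivity",
    "distal_bed",
    "embolism",
    "ldl",
    "smoking",
    "exsmoker",
    "hypertension",
    "blood_pressure",
    "diabetes",
    "other_pad_history",
    "family_history",
    "current_treatment",
)

BINARY_FIELDS = (
    "distal_bed",
    "smoking",
    "exsmoker",
    "hypertension",
    "diabetes",
    "other_pad_history",
    "family_history",
    "current_treatment",
)

N_FEATURES = len(FEATURE_NAMES)


def encode_blood_pressure(systolic: float, diastolic: float) -> int:
    """Map a systolic/diastolic pair (mmHg) onto the adult staging scale.

    0 = normal, 1 = prehypertension, 2 = stage I, 3 = stage II.  Band edges
    are closed on the printed limits (120-139 means 120 <= v <= 139; 160 mmHg
    systolic or 100 mmHg diastolic already counts as stage II, so the scale
    has no gaps).  When the two pressures fall into different bands the higher
    stage wins, the usual clinical staging convention.
    """
    if not (systolic > 0 and diastolic > 0):
        raise InvalidRecordError(
            f"blood pressures must be positive, got {systolic}/{diastolic}"
        )

    def _sys_band(v: float) -> int:
        if v < 120:
            return 0
        if v <= 139:
            return 1
        if v <= 159:
            return 2
        return 3

    def _dia_band(v: float) -> int:
        if v < 80:
            return 0
        if v <= 89:
            return 1
        if v <= 99:
            return 2
        return 3

    return max(_sys_band(systolic), _dia_band(diastolic))


def encode_ldl(ldl: float) -> int:
    """Map LDL cholesterol (mg/dL) onto the adult category scale 0..4.

    0 = optimal (<100), 1 = near/above optimal (100-129), 2 = borderline
    high (130-159), 3 = high (160-189), 4 = very high (>=190).
    """
    if not ldl > 0:
        raise InvalidRecordError(f"LDL must be positive, got {ldl}")
    if ldl < 100:
        return 0
    if ldl <= 129:
        return 1
    if ldl <= 159:
        return 2
    if ldl <= 189:
        return 3
    return 4


@dataclass
class PatientRecord:
    """Raw clinical fields of one patient plus the (optional) treatment label.

    LDL may be given either as a raw mg/dL value (``ldl_mgdl``) or a
    pre-assigned category (``ldl_category``); blood pressure either as the
    measured ``systolic``/``diastolic`` pair or a pre-assigned
    ``blood_pressure_category``.  Exactly one representation must be present
    for each.
    """

    age: int
    sex: str
    fontaine_stage: str
    lesion_type: str
    anesthesia_sensitivity: str
    distal_bed: str
    embolism: float
    smoking: str
    exsmoker: str
    hypertension: str
    diabetes: str
    other_pad_history: str
    family_history: str
    current_treatment: str
    ldl_mgdl: Optional[float] = None
    ldl_category: Optional[int] = None
    systolic: Optional[float] = None
    diastolic: Optional[float] = None
    blood_pressure_category: Optional[int] = None
    decision: Optional[str] = None

    def validate(self) -> None:
        if not (0 < self.age < 130):
            raise InvalidRecordError(f"age out of range (0, 130): {self.age}")
        if self.sex not in SEX_CODES:
            raise InvalidRecordError(f"unknown sex token: {self.sex!r}")
        if self.fontaine_stage not in FONTAINE_CODES:
            raise InvalidRecordError(
                f"unknown Fontaine stage: {self.fontaine_stage!r}"
            )
        if self.lesion_type not in LESION_CODES:
            raise InvalidRecordError(f"unknown TASC lesion type: {self.lesion_type!r}")
        if self.anesthesia_sensitivity not in ANESTHESIA_CODES:
            raise InvalidRecordError(
                f"unknown anesthesia sensitivity: {self.anesthesia_sensitivity!r}"
            )
        if not (0 <= self.embolism <= 100):
            raise InvalidRecordError(f"embolism % out of [0, 100]: {self.embolism}")
        for name in BINARY_FIELDS:
            tok = getattr(self, name)
            if tok not in BINARY_CODES:
                raise InvalidRecordError(f"field {name}: unknown token {tok!r}")

        has_raw_ldl = self.ldl_mgdl is not None
        has_cat_ldl = self.ldl_category is not None
        if has_raw_ldl == has_cat_ldl:
            raise InvalidRecordError(
                "exactly one of ldl_mgdl / ldl_category must be given"
            )
        if has_cat_ldl and self.ldl_category not in range(5):
            raise InvalidRecordError(f"LDL category out of 0..4: {self.ldl_category}")

        has_raw_bp = self.systolic is not None or self.diastolic is not None
        has_cat_bp = self.blood_pressure_category is not None
        if has_raw_bp == has_cat_bp:
            raise InvalidRecordError(
                "exactly one of systolic+diastolic / blood_pressure_category "
                "must be given"
            )
        if has_raw_bp:
            if self.systolic is None or self.diastolic is None:
                raise InvalidRecordError("both systolic and diastolic are required")
            if not self.systolic > self.diastolic:
                raise InvalidRecordError(
                    f"systolic must exceed diastolic: {self.systolic}/{self.diastolic}"
                )
        if has_cat_bp and self.blood_pressure_category not in range(4):
            raise InvalidRecordError(
                f"blood-pressure category out of 0..3: {self.blood_pressure_category}"
            )
        if self.decision is not None and self.decision not in LABEL_CODES:
            raise InvalidRecordError(f"unknown decision token: {self.decision!r}")


@dataclass
class FeatureVector:
    """The 16 encoded inputs of one patient, in code-table row order."""

    x: tuple
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.x = tuple(float(v) for v in self.x)
        if len(self.x) != N_FEATURES:
            raise InvalidRecordError(f"expected {N_FEATURES} features, got {len(self.x)}")
        if self.label is not None and self.label not in (-1, 1):
            raise InvalidRecordError(f"label must be -1 or +1, got {self.label}")


def encode_record(rec: PatientRecord) -> FeatureVector:
    """Encode one validated patient record into its 16-slot feature vector."""
    rec.validate()
    ldl = rec.ldl_category if rec.ldl_category is not None else encode_ldl(rec.ldl_mgdl)
    if rec.blood_pressure_category is not None:
        bp = rec.blood_pressure_category
    else:
        bp = encode_blood_pressure(rec.systolic, rec.diastolic)
    x = (
        rec.age / 100.0,
        SEX_CODES[rec.sex],
        FONTAINE_CODES[rec.fontaine_stage],
        LESION_CODES[rec.lesion_type],
        ANESTHESIA_CODES[rec.anesthesia_sensitivity],
        BINARY_CODES[rec.distal_bed],
        rec.embolism / 100.0,
        ldl,
        BINARY_CODES[rec.smoking],
        BINARY_CODES[rec.exsmoker],
        BINARY_CODES[rec.hypertension],
        bp,
        BINARY_CODES[rec.diabetes],
        BINARY_CODES[rec.other_pad_history],
        BINARY_CODES[rec.family_history],
        BINARY_CODES[rec.current_treatment],
    )
    label = None if rec.decision is None else LABEL_CODES[rec.decision]
    return FeatureVector(x=x, label=label)


def encode_cohort(records: Iterable[PatientRecord]) -> list[FeatureVector]:
    return [encode_record(r) for r in records]


def features_matrix(vectors: Sequence[FeatureVector]):
    """Stack feature vectors into (X, y); y entries are NaN where unlabeled."""
    X = np.array([v.x for v in vectors], dtype=float)
    y = np.array(
        [math.nan if v.label is None else float(v.label) for v in vectors]
    )
    return X, y


# ---------------------------------------------------------------------------
# File I/O.  Cohorts travel as plain CSV with a header row; category fields
# use lowercase tokens and the two dual-representation fields (LDL, blood
# pressure) leave the unused columns empty.

_COHORT_COLUMNS = [
    "age", "sex", "fontaine_stage", "lesion_type", "anesthesia_sensitivity",
    "distal_bed", "embolism", "ldl_mgdl", "ldl_category", "smoking",
    "exsmoker", "hypertension", "systolic", "diastolic",
    "blood_pressure_category", "diabetes", "other_pad_history",
    "family_history", "current_treatment", "decision",
]


def _opt(value: str, caster):
    value = value.strip()
    return None if value == "" else caster(value)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated patient records.

    Malformed rows raise :class:`InvalidRecordError` carrying the 1-based data
    row number.  An empty or header-only file yields an empty list.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            rec = PatientRecord(
                age=int(row["age"]),
                sex=row["sex"].strip(),
                fontaine_stage=row["fontaine_stage"].strip(),
                lesion_type=row["lesion_type"].strip(),
                anesthesia_sensitivity=row["anesthesia_sensitivity"].strip(),
                distal_bed=row["distal_bed"].strip(),
                embolism=float(row["embolism"]),
                ldl_mgdl=_opt(row.get("ldl_mgdl", ""), float),
                ldl_category=_opt(row.get("ldl_category", ""), int),
                smoking=row["smoking"].strip(),
                exsmoker=row["exsmoker"].strip(),
                hypertension=row["hypertension"].strip(),
                systolic=_opt(row.get("systolic", ""), float),
                diastolic=_opt(row.get("diastolic", ""), float),
                blood_pressure_category=_opt(
                    row.get("blood_pressure_category", ""), int
                ),
                diabetes=row["diabetes"].strip(),
                other_pad_history=row["other_pad_history"].strip(),
                family_history=row["family_history"].strip(),
                current_treatment=row["current_treatment"].strip(),
                decision=_opt(row.get("decision", ""), str) or None,
            )
            rec.validate()
        except (KeyError, ValueError, AttributeError) as exc:
            raise InvalidRecordError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_cohort(path, records: Iterable[PatientRecord]) -> None:
    rows = []
    for rec in records:
        rows.append({
            "age": rec.age,
            "sex": rec.sex,
            "fontaine_stage": rec.fontaine_stage,
            "lesion_type": rec.lesion_type,
            "anesthesia_sensitivity": rec.anesthesia_sensitivity,
            "distal_bed": rec.distal_bed,
            "embolism": rec.embolism,
            "ldl_mgdl": "" if rec.ldl_mgdl is None else rec.ldl_mgdl,
            "ldl_category": "" if rec.ldl_category is None else rec.ldl_category,
            "smoking": rec.smoking,
            "exsmoker": rec.exsmoker,
            "hypertension": rec.hypertension,
            "systolic": "" if rec.systolic is None else rec.systolic,
            "diastolic": "" if rec.diastolic is None else rec.diastolic,
            "blood_pressure_category": (
                "" if rec.blood_pressure_category is None
                else rec.blood_pressure_category
            ),
            "diabetes": rec.diabetes,
            "other_pad_history": rec.other_pad_history,
            "family_history": rec.family_history,
            "current_treatment": rec.current_treatment,
            "decision": rec.decision or "",
        })
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def write_features(path, vectors: Sequence[FeatureVector]) -> None:
    """Write encoded feature vectors as CSV: 16 numeric columns + decision."""
    X, y = features_matrix(vectors)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["decision"] = ["" if math.isnan(v) else int(v) for v in y]
    df.to_csv(path, index=False)


def read_features(path) -> list[FeatureVector]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    vectors = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            x = tuple(float(row[name]) for name in FEATURE_NAMES)
            label = _opt(row.get("decision", ""), lambda s: int(float(s)))
            vectors.append(FeatureVector(x=x, label=label))
        except (KeyError, ValueError) as exc:
            raise InvalidRecordError(f"row {i}: {exc}") from exc
    return vectors
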