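"""Reproducible transplant-EHR-like relational source generator.

Emulates the shape of a kidney-transplant documentation system: patients and
donors joined through a central transplantation table, longitudinal lab
panels with units, diagnoses and medications hanging off the transplantation,
examinations that reference only the patient, and free-text findings. All
five table types the ETL distinguishes are present:

* ``LabValue`` — already EAV (one analyte per row) and unit-bearing;
* ``Diagnosis``, ``Medication``, ``Finding`` — reach the transplantation
  through a foreign key (``Finding`` additionally carries free-text blobs);
* ``Examination`` — no path to the transplantation at all;
* ``Transplantation`` itself — the anchor.

For each bundled cohort study the generator *plants* a requested number of
patients that satisfy the study's criteria by construction; the recorded
truth set is then the independent SQL oracle's answer over the emitted
database (planted patients are always contained in it). Some examinations
are deliberately placed outside every transplantation window so the
surrogate-encounter logic is always exercised. Dates are ISO-8601 days; the
same seed yields identical output.

Default scale (200 patients, about fifty thousand value cells) is a
desk-scale stand-in; :func:`scale_profile` derives configs whose expected
per-entity counts are a fixed fraction of a large production registry
(thousands of patients, millions of lab values).
"""

from __future__ import annotations

import datetime as dt
import json
import math
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import oracle

__all__ = [
    "Analyte",
    "GeneratorConfig",
    "PlantedTruth",
    "generate",
    "scale_profile",
    "default_schema_config",
    "SOURCE_TABLES",
]

SOURCE_TABLES = (
    "Patient",
    "Donor",
    "Transplantation",
    "LabValue",
    "Diagnosis",
    "Examination",
    "Finding",
    "Medication",
)

#: Reference per-entity totals of a large production transplant registry
#: (18 years of documentation) used by :func:`scale_profile` to derive
#: realistic per-patient rates.
REFERENCE_COUNTS = {
    "patients": 3493,
    "transplants": 3767,
    "diagnoses": 54009,
    "medications": 182250,
    "lab_values": 8652557,
}


@dataclass(frozen=True)
class Analyte:
    code: str
    unit: str
    dist: str  # "normal" | "lognormal"
    p1: float
    p2: float
    weight: float = 1.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "normal":
            return float(max(0.1, rng.normal(self.p1, self.p2)))
        return float(rng.lognormal(self.p1, self.p2))


DEFAULT_PANEL = (
    Analyte("CREA", "mg/dl", "lognormal", 0.10, 0.35),
    Analyte("UREA", "mg/dl", "normal", 40.0, 12.0),
    Analyte("HB", "g/dl", "normal", 12.5, 1.8),
    Analyte("NA", "mmol/l", "normal", 140.0, 3.0, weight=0.8),
    Analyte("K", "mmol/l", "normal", 4.3, 0.5, weight=0.8),
    Analyte("CRP", "mg/l", "lognormal", 1.0, 1.0, weight=0.6),
    Analyte("UACR", "mg/g", "lognormal", 3.0, 0.8, weight=0.4),
)

DEFAULT_DIAGNOSES = ("CKD2", "CKD3", "CKD4", "HTN", "DM2", "GN", "PKD")
DEFAULT_DRUGS = ("TAC", "MMF", "PRED", "CYA", "AZA")
DEFAULT_KEYWORDS = ("urinary tract infection", "pneumonia", "wound healing disorder")
EXAM_TYPES = (("FOLLOWUP", 0.6), ("ULTRASOUND", 0.25), ("BIOPSY", 0.15))

FINDING_TEMPLATES = (
    "Clinical course after renal transplantation reviewed. {detail} Graft perfusion regular.",
    "Status post kidney transplantation. {detail} No acute intervention required.",
    "Follow-up assessment. {detail} Laboratory trend discussed with the patient.",
)
FILLER_DETAILS = (
    "No signs of acute rejection.",
    "Mild perirenal fluid collection, stable.",
    "Blood pressure well controlled under current medication.",
    "Patient reports good general condition.",
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic source; defaults are the study conditions.

    Per-patient counts are Poisson with the given means; the transplant
    count is 1 + Poisson(mean − 1) so every registry patient has at least
    one transplant. ``planted_cohorts`` maps bundled study id → number of
    guaranteed-qualifying patients.
    """

    seed: int = 1234
    n_patients: int = 200
    transplants_per_patient_mean: float = 1.08
    organ_failure_prob: float = 0.25
    pancreas_prob: float = 0.10
    tests_per_patient_mean: float = 55.0
    analytes_per_test: tuple[int, int] = (3, 6)
    analyte_panel: tuple[Analyte, ...] = DEFAULT_PANEL
    hcv_test_prob: float = 0.30
    hcv_positive_prob: float = 0.15
    diagnoses_per_patient_mean: float = 4.0
    diagnosis_codes: tuple[str, ...] = DEFAULT_DIAGNOSES
    death_prob: float = 0.08
    medications_per_patient_mean: float = 6.0
    drug_codes: tuple[str, ...] = DEFAULT_DRUGS
    esa_patient_prob: float = 0.20
    examinations_per_patient_mean: float = 5.0
    exam_result_null_prob: float = 0.30
    findings_per_transplant_mean: float = 1.5
    keyword_prob: float = 0.25
    uti_after_failure_prob: float = 0.60
    finding_keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    planted_cohorts: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 8, 3: 7, 4: 6}
    )
    date_range: tuple[str, str] = ("2000-01-01", "2017-12-31")

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.organ_failure_prob <= 1.0:
            raise ValueError("organ_failure_prob must be a probability")
        if self.transplants_per_patient_mean < 1.0:
            raise ValueError("transplants_per_patient_mean must be >= 1")
        start, end = (dt.date.fromisoformat(d) for d in self.date_range)
        if start >= end:
            raise ValueError("date_range start must precede end")
        if sum(self.planted_cohorts.values()) > self.n_patients:
            raise ValueError(
                f"planted cohorts need {sum(self.planted_cohorts.values())} patients "
                f"but n_patients is {self.n_patients}"
            )
        for sid in self.planted_cohorts:
            if sid not in (1, 2, 3, 4):
                raise ValueError(f"unknown bundled study id {sid}")

    # ------------------------------------------------------------------
    def expected_counts(self) -> dict[str, tuple[float, float]]:
        """Per-entity expected row counts and standard deviations.

        Derived from the config's own distributions (Poisson counts,
        uniform panel size); used by the generator's distributional
        self-checks.
        """
        n = self.n_patients
        m_tx = self.transplants_per_patient_mean
        kmin, kmax = self.analytes_per_test
        ks = np.arange(kmin, kmax + 1)
        ek, ek2 = float(ks.mean()), float((ks**2).mean())
        t = self.tests_per_patient_mean
        lab_mean = t * ek + self.hcv_test_prob
        lab_var = t * ek2 + self.hcv_test_prob * (1 - self.hcv_test_prob)
        diag_mean = (
            self.diagnoses_per_patient_mean
            + m_tx * self.organ_failure_prob
            + self.death_prob
        )
        diag_var = (
            self.diagnoses_per_patient_mean
            + m_tx * self.organ_failure_prob
            + self.death_prob * (1 - self.death_prob)
        )
        find_mean = m_tx * (
            self.findings_per_transplant_mean
            + self.organ_failure_prob * self.uti_after_failure_prob
        )
        exam_mean = self.examinations_per_patient_mean + 0.1  # surrogate-zone extras
        return {
            "Patient": (float(n), 0.0),
            "Transplantation": (n * m_tx, math.sqrt(max(n * (m_tx - 1.0), 1e-9))),
            "LabValue": (n * lab_mean, math.sqrt(n * lab_var)),
            "Diagnosis": (n * diag_mean, math.sqrt(n * diag_var)),
            "Medication": (
                n * self.medications_per_patient_mean,
                math.sqrt(n * self.medications_per_patient_mean),
            ),
            "Examination": (n * exam_mean, math.sqrt(n * exam_mean)),
            "Finding": (n * find_mean, math.sqrt(n * find_mean * 2.0)),
        }


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated database."""

    per_entity_row_counts: dict[str, int]
    per_study_patients: dict[int, list[int]]
    per_patient_transplants: dict[int, list[tuple[int, str, Optional[str]]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_entity_row_counts": self.per_entity_row_counts,
                "per_study_patients": {
                    str(k): sorted(v) for k, v in self.per_study_patients.items()
                },
                "per_patient_transplants": {
                    str(k): [list(t) for t in v]
                    for k, v in self.per_patient_transplants.items()
                },
            },
            indent=1,
        )


def scale_profile(
    factor: float, seed: int = 1234, allow_upscale: bool = False
) -> GeneratorConfig:
    """Config whose expected entity counts are ``factor`` times the
    reference registry's totals.

    ``factor`` above 1 is rejected unless explicitly allowed (desk-scale
    guard).
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    if factor > 1 and not allow_upscale:
        raise ValueError("factor > 1 rejected; pass allow_upscale=True to override")
    n = round(REFERENCE_COUNTS["patients"] * factor)
    per_patient = {
        k: REFERENCE_COUNTS[k] / REFERENCE_COUNTS["patients"]
        for k in ("transplants", "diagnoses", "medications", "lab_values")
    }
    kmin, kmax = 3, 6
    mean_k = (kmin + kmax) / 2.0
    return GeneratorConfig(
        seed=seed,
        n_patients=n,
        transplants_per_patient_mean=per_patient["transplants"],
        diagnoses_per_patient_mean=max(
            per_patient["diagnoses"]
            - per_patient["transplants"] * 0.25  # rejection diagnoses
            - 0.08,  # death indicators
            0.0,
        ),
        medications_per_patient_mean=per_patient["medications"],
        tests_per_patient_mean=max((per_patient["lab_values"] - 0.30) / mean_k, 0.0),
        analytes_per_test=(kmin, kmax),
        planted_cohorts={},
    )


# ---------------------------------------------------------------------------
# schema config for the generated database

def default_schema_config(concept_prefix: str = "SRC") -> dict:
    """Schema/role-map config describing the generated source database."""
    return {
        "anchor_table": "Transplantation",
        "patient_table": "Patient",
        "tables": {
            "Patient": {
                "primary_key": ["patient_id"],
                "columns": [
                    {"name": "patient_id", "role": "KEY"},
                    {"name": "birth_date", "role": "METADATA"},
                    {"name": "sex", "role": "METADATA"},
                ],
            },
            "Donor": {
                "primary_key": ["donor_id"],
                "columns": [
                    {"name": "donor_id", "role": "KEY"},
                    {"name": "birth_date", "role": "METADATA"},
                    {"name": "sex", "role": "METADATA"},
                ],
            },
            "Transplantation": {
                "primary_key": ["transplant_id"],
                "columns": [
                    {"name": "transplant_id", "role": "KEY"},
                    {"name": "patient_id", "role": "PATIENT_REF"},
                    {"name": "donor_id", "role": "KEY"},
                    {"name": "organ", "role": "VALUE", "categorical": True},
                    {"name": "transplant_date", "role": "DATE"},
                    {"name": "failure_date", "role": "METADATA", "nullable": True},
                ],
                "foreign_keys": [
                    {"column": "patient_id", "references": "Patient.patient_id"},
                    {"column": "donor_id", "references": "Donor.donor_id"},
                ],
            },
            "LabValue": {
                "primary_key": ["lab_id"],
                "columns": [
                    {"name": "lab_id", "role": "KEY"},
                    {"name": "patient_id", "role": "PATIENT_REF"},
                    {"name": "test_id", "role": "EVENT_KEY"},
                    {"name": "lab_date", "role": "DATE"},
                    {"name": "analyte_code", "role": "CONCEPT"},
                    {"name": "value_num", "role": "VALUE", "numeric": True},
                    {"name": "unit", "role": "UNIT", "unit_of": "value_num"},
                ],
                "foreign_keys": [
                    {"column": "patient_id", "references": "Patient.patient_id"},
                ],
            },
            "Diagnosis": {
                "primary_key": ["diag_id"],
                "columns": [
                    {"name": "diag_id", "role": "KEY"},
                    {"name": "transplant_id", "role": "KEY"},
                    {"name": "diag_code", "role": "VALUE", "categorical": True},
                    {"name": "diag_date", "role": "DATE"},
                ],
                "foreign_keys": [
                    {"column": "transplant_id", "references": "Transplantation.transplant_id"},
                ],
            },
            "Examination": {
                "primary_key": ["exam_id"],
                "columns": [
                    {"name": "exam_id", "role": "KEY"},
                    {"name": "patient_id", "role": "PATIENT_REF"},
                    {"name": "exam_date", "role": "DATE"},
                    {"name": "exam_type", "role": "VALUE", "categorical": True},
                    {"name": "result_num", "role": "VALUE", "numeric": True, "nullable": True},
                ],
                "foreign_keys": [
                    {"column": "patient_id", "references": "Patient.patient_id"},
                ],
            },
            "Finding": {
                "primary_key": ["finding_id"],
                "columns": [
                    {"name": "finding_id", "role": "KEY"},
                    {"name": "transplant_id", "role": "KEY"},
                    {"name": "finding_date", "role": "DATE"},
                    {"name": "finding_text", "role": "FREE_TEXT"},
                ],
                "foreign_keys": [
                    {"column": "transplant_id", "references": "Transplantation.transplant_id"},
                ],
            },
            "Medication": {
                "primary_key": ["med_id"],
                "columns": [
                    {"name": "med_id", "role": "KEY"},
                    {"name": "transplant_id", "role": "KEY"},
                    {"name": "drug_code", "role": "VALUE", "categorical": True},
                    {"name": "start_date", "role": "DATE"},
                    {"name": "end_date", "role": "METADATA", "nullable": True},
                ],
                "foreign_keys": [
                    {"column": "transplant_id", "references": "Transplantation.transplant_id"},
                ],
            },
        },
    }


# ---------------------------------------------------------------------------
# generation

_DDL = """
CREATE TABLE Patient (patient_id INTEGER PRIMARY KEY, birth_date TEXT, sex TEXT);
CREATE TABLE Donor (donor_id INTEGER PRIMARY KEY, birth_date TEXT, sex TEXT);
CREATE TABLE Transplantation (
    transplant_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES Patient(patient_id),
    donor_id INTEGER NOT NULL REFERENCES Donor(donor_id),
    organ TEXT NOT NULL,
    transplant_date TEXT NOT NULL,
    failure_date TEXT
);
CREATE TABLE LabValue (
    lab_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES Patient(patient_id),
    test_id INTEGER NOT NULL,
    lab_date TEXT NOT NULL,
    analyte_code TEXT NOT NULL,
    value_num REAL,
    unit TEXT
);
CREATE TABLE Diagnosis (
    diag_id INTEGER PRIMARY KEY,
    transplant_id INTEGER NOT NULL REFERENCES Transplantation(transplant_id),
    diag_code TEXT NOT NULL,
    diag_date TEXT NOT NULL
);
CREATE TABLE Examination (
    exam_id INTEGER PRIMARY KEY,
    patient_id INTEGER NOT NULL REFERENCES Patient(patient_id),
    exam_date TEXT NOT NULL,
    exam_type TEXT NOT NULL,
    result_num REAL
);
CREATE TABLE Finding (
    finding_id INTEGER PRIMARY KEY,
    transplant_id INTEGER NOT NULL REFERENCES Transplantation(transplant_id),
    finding_date TEXT NOT NULL,
    finding_text TEXT NOT NULL
);
CREATE TABLE Medication (
    med_id INTEGER PRIMARY KEY,
    transplant_id INTEGER NOT NULL REFERENCES Transplantation(transplant_id),
    drug_code TEXT NOT NULL,
    start_date TEXT NOT NULL,
    end_date TEXT
);
"""


class _Ids:
    def __init__(self) -> None:
        self._next: dict[str, int] = {}

    def take(self, kind: str) -> int:
        n = self._next.get(kind, 0) + 1
        self._next[kind] = n
        return n


def _iso(day: dt.date) -> str:
    return day.isoformat()


def _plan_for(config: GeneratorConfig) -> dict[int, int]:
    """Assign planted study membership to the lowest patient ids."""
    plan: dict[int, int] = {}
    pid = 1
    for sid in sorted(config.planted_cohorts):
        for _ in range(config.planted_cohorts[sid]):
            plan[pid] = sid
            pid += 1
    return plan


def generate(
    config: GeneratorConfig,
    out_path: Path | str,
    csv_dir: Optional[Path | str] = None,
) -> tuple[Path, PlantedTruth]:
    """Emit the source database (SQLite, optionally also CSV) plus truth.

    The truth sidecar (``<out>.truth.json``) records exact per-table value
    cell counts, each patient's ordered transplants, and — for each planted
    study — the SQL-oracle patient set over the emitted data.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    conn = sqlite3.connect(str(out_path))
    conn.executescript(_DDL)
    rng = np.random.default_rng(config.seed)
    ids = _Ids()
    start, end = (dt.date.fromisoformat(d) for d in config.date_range)
    span = (end - start).days
    plan = _plan_for(config)
    p3 = oracle.STUDY_PARAMS[3]
    p4 = oracle.STUDY_PARAMS[4]

    per_patient_tx: dict[int, list[tuple[int, str, Optional[str]]]] = {}

    def rand_day(lo: dt.date, hi: dt.date) -> dt.date:
        d = (hi - lo).days
        return lo + dt.timedelta(days=int(rng.integers(0, max(d, 0) + 1)))

    patients, donors, transplants = [], [], []
    labs, diagnoses, exams, findings, meds = [], [], [], [], []

    for pid in range(1, config.n_patients + 1):
        study = plan.get(pid)
        patients.append((pid, _iso(rand_day(start - dt.timedelta(days=25000), start)),
                         "F" if rng.random() < 0.45 else "M"))

        # --- transplants -------------------------------------------------
        n_tx = 1 + int(rng.poisson(config.transplants_per_patient_mean - 1.0))
        if study == 4:
            n_tx = 1
        tx_lo = start
        if study == 3:
            tx_lo = max(start, dt.date.fromisoformat(p3["window_start"]))
        if study == 4:
            tx_lo = max(start, dt.date.fromisoformat(p4["transplant_after"]))
        tx_hi = end - dt.timedelta(days=420)
        first_dates: set[dt.date] = set()
        dates: list[dt.date] = []
        while len(dates) < n_tx:
            d = rand_day(tx_lo, tx_hi)
            if d not in first_dates:
                first_dates.add(d)
                dates.append(d)
        dates.sort()
        tx_records = []
        for i, d in enumerate(dates):
            tid = ids.take("tx")
            did = ids.take("donor")
            donors.append((did, _iso(rand_day(start - dt.timedelta(days=20000), start)),
                           "F" if rng.random() < 0.5 else "M"))
            organ = "PANCREAS" if rng.random() < config.pancreas_prob else "KIDNEY"
            if study == 3:
                organ = "KIDNEY"
            failed = rng.random() < config.organ_failure_prob
            failure: Optional[dt.date] = None
            if study == 3 and i == 0:
                failed = True
            if failed:
                failure = d + dt.timedelta(days=int(rng.integers(200, 381)))
            transplants.append((tid, pid, did, organ, _iso(d), _iso(failure) if failure else None))
            tx_records.append((tid, d, failure))
            if failure is not None:
                diagnoses.append((ids.take("diag"), tid, "REJ", _iso(failure)))
        per_patient_tx[pid] = [(t, _iso(d), _iso(f) if f else None) for t, d, f in tx_records]
        first_tx_id, first_tx, first_failure = tx_records[0]

        # --- labs --------------------------------------------------------
        lab_hi = end
        if study == 4:
            lab_hi = first_tx + dt.timedelta(days=180)
        n_tests = int(rng.poisson(config.tests_per_patient_mean))
        kmin, kmax = config.analytes_per_test
        weights = np.array([a.weight for a in config.analyte_panel])
        weights = weights / weights.sum()
        for _ in range(n_tests):
            test_id = ids.take("test")
            d = rand_day(start, lab_hi)
            k = int(rng.integers(kmin, kmax + 1))
            chosen = rng.choice(
                len(config.analyte_panel), size=min(k, len(config.analyte_panel)),
                replace=False, p=weights,
            )
            for idx in sorted(chosen):
                a = config.analyte_panel[idx]
                labs.append((ids.take("lab"), pid, test_id, _iso(d), a.code,
                             round(a.draw(rng), 2), a.unit))
        if rng.random() < config.hcv_test_prob or study == 2:
            positive = rng.random() < config.hcv_positive_prob
            if study == 2:
                positive = True
            value = round(float(rng.lognormal(1.5, 0.5)), 2) if positive else 0.0
            labs.append((ids.take("lab"), pid, ids.take("test"),
                         _iso(rand_day(start, lab_hi)), "HCV", value, "titer"))
        if study == 1:
            test_id = ids.take("test")
            d = first_tx + dt.timedelta(days=30)
            for code, val, unit in (
                ("CREA", 2.5, "mg/dl"), ("UREA", 48.0, "mg/dl"), ("HB", 12.5, "g/dl"),
            ):
                labs.append((ids.take("lab"), pid, test_id, _iso(d), code, val, unit))
        if study == 4:
            test_id = ids.take("test")
            d = first_tx + dt.timedelta(days=200)
            labs.append((ids.take("lab"), pid, test_id, _iso(d), "HB", 12.0, "g/dl"))
            labs.append((ids.take("lab"), pid, test_id, _iso(d), "UACR", 25.0, "mg/g"))

        # --- diagnoses ---------------------------------------------------
        n_diag = int(rng.poisson(config.diagnoses_per_patient_mean))
        for _ in range(n_diag):
            tid, txd, _f = tx_records[int(rng.integers(0, len(tx_records)))]
            code = config.diagnosis_codes[int(rng.integers(0, len(config.diagnosis_codes)))]
            diagnoses.append((ids.take("diag"), tid, code,
                              _iso(rand_day(txd, min(txd + dt.timedelta(days=1500), end)))))
        if study == 4:
            diagnoses.append((ids.take("diag"), first_tx_id, p4["ckd_code"],
                              _iso(first_tx + dt.timedelta(days=50))))
        if study != 2 and rng.random() < config.death_prob:
            last_tid, last_txd, _f = tx_records[-1]
            diagnoses.append((ids.take("diag"), last_tid, "DEATH",
                              _iso(rand_day(last_txd, end))))

        # --- examinations ------------------------------------------------
        n_exam = int(rng.poisson(config.examinations_per_patient_mean))
        type_names = [t for t, _ in EXAM_TYPES]
        type_p = np.array([p for _, p in EXAM_TYPES])
        for _ in range(n_exam):
            ety = type_names[int(rng.choice(len(type_names), p=type_p))]
            res = None
            if rng.random() >= config.exam_result_null_prob:
                res = round(float(rng.normal(50.0, 10.0)), 1)
            exams.append((ids.take("exam"), pid, _iso(rand_day(start, end)), ety, res))
        if pid % 10 == 0:
            # deliberately outside every window: before first transplant lead
            exams.append((ids.take("exam"), pid,
                          _iso(first_tx - dt.timedelta(days=60)), "ULTRASOUND", 42.0))
        if study == 2:
            exams.append((ids.take("exam"), pid,
                          _iso(first_tx + dt.timedelta(days=45)), "FOLLOWUP", 50.0))

        # --- findings ----------------------------------------------------
        for tid, txd, failure in tx_records:
            n_find = int(rng.poisson(config.findings_per_transplant_mean))
            for _ in range(n_find):
                template = FINDING_TEMPLATES[int(rng.integers(0, len(FINDING_TEMPLATES)))]
                if rng.random() < config.keyword_prob:
                    detail = "Evidence of " + config.finding_keywords[
                        int(rng.integers(0, len(config.finding_keywords)))
                    ] + "."
                else:
                    detail = FILLER_DETAILS[int(rng.integers(0, len(FILLER_DETAILS)))]
                findings.append((ids.take("finding"), tid,
                                 _iso(rand_day(txd, min(txd + dt.timedelta(days=1200), end))),
                                 template.format(detail=detail)))
            if failure is not None and rng.random() < config.uti_after_failure_prob:
                mid = txd + dt.timedelta(days=(failure - txd).days // 2)
                findings.append((ids.take("finding"), tid, _iso(mid),
                                 "Febrile episode with evidence of urinary tract infection."))
        if study == 3:
            _tid, txd, failure = tx_records[0]
            mid = txd + dt.timedelta(days=int((failure - txd).days // 2))
            findings.append((ids.take("finding"), first_tx_id, _iso(mid),
                             "Dysuria and fever; urinary tract infection confirmed by culture."))

        # --- medications -------------------------------------------------
        n_med = int(rng.poisson(config.medications_per_patient_mean))
        esa_user = rng.random() < config.esa_patient_prob and study != 4
        drug_pool = list(config.drug_codes) + (["ESA"] if esa_user else [])
        for _ in range(n_med):
            tid, txd, _f = tx_records[int(rng.integers(0, len(tx_records)))]
            drug = drug_pool[int(rng.integers(0, len(drug_pool)))]
            s = txd + dt.timedelta(days=int(rng.integers(0, 601)))
            e = None
            if rng.random() < 0.8:
                e = s + dt.timedelta(days=int(rng.integers(10, 401)))
            meds.append((ids.take("med"), tid, drug, _iso(s), _iso(e) if e else None))

    with conn:
        conn.executemany("INSERT INTO Patient VALUES (?,?,?)", patients)
        conn.executemany("INSERT INTO Donor VALUES (?,?,?)", donors)
        conn.executemany("INSERT INTO Transplantation VALUES (?,?,?,?,?,?)", transplants)
        conn.executemany("INSERT INTO LabValue VALUES (?,?,?,?,?,?,?)", labs)
        conn.executemany("INSERT INTO Diagnosis VALUES (?,?,?,?)", diagnoses)
        conn.executemany("INSERT INTO Examination VALUES (?,?,?,?,?)", exams)
        conn.executemany("INSERT INTO Finding VALUES (?,?,?,?)", findings)
        conn.executemany("INSERT INTO Medication VALUES (?,?,?,?,?)", meds)

    truth = PlantedTruth(
        per_entity_row_counts=_value_cell_counts(conn),
        per_study_patients={
            sid: sorted(oracle.eval_study_on_source(conn, sid))
            for sid in sorted(config.planted_cohorts)
        },
        per_patient_transplants=per_patient_tx,
    )
    out_path.with_suffix(out_path.suffix + ".truth.json").write_text(truth.to_json())

    if csv_dir is not None:
        export_source_csv(conn, csv_dir)
    conn.close()
    return out_path, truth


def _value_cell_counts(conn: sqlite3.Connection) -> dict[str, int]:
    """Exact non-null value-cell count per fact-bearing table."""
    queries = {
        "Transplantation": 'SELECT COUNT(organ) FROM Transplantation',
        "LabValue": 'SELECT COUNT(value_num) FROM LabValue',
        "Diagnosis": 'SELECT COUNT(diag_code) FROM Diagnosis',
        "Examination": 'SELECT COUNT(exam_type) + COUNT(result_num) FROM Examination',
        "Finding": 'SELECT COUNT(finding_text) FROM Finding',
        "Medication": 'SELECT COUNT(drug_code) FROM Medication',
    }
    return {t: conn.execute(q).fetchone()[0] for t, q in queries.items()}


def export_source_csv(conn: sqlite3.Connection, outdir: Path | str) -> list[Path]:
    """Write one RFC-4180 CSV per source table (header row, ISO dates)."""
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for table in SOURCE_TABLES:
        cur = conn.execute(f'SELECT * FROM "{table}" ORDER BY rowid')
        cols = [d[0] for d in cur.description]
        dest = outdir / f"{table}.csv"
        with dest.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            w.writerows(cur)
        written.append(dest)
    return written


def load_source_csv(csv_dir: Path | str, target: Path | str) -> Path:
    """Build a SQLite source database from a directory of per-table CSVs."""
    import csv

    csv_dir = Path(csv_dir)
    target = Path(target)
    if target.exists():
        target.unlink()
    conn = sqlite3.connect(str(target))
    conn.executescript(_DDL)
    with conn:
        for table in SOURCE_TABLES:
            path = csv_dir / f"{table}.csv"
            if not path.exists():
                continue
            with path.open(newline="") as fh:
                reader = csv.reader(fh)
                header = next(reader)
                rows = [[None if v == "" else v for v in row] for row in reader]
            conn.executemany(
                f'INSERT INTO "{table}" ({", ".join(header)}) '
                f'VALUES ({", ".join("?" * len(header))})',
                rows,
            )
    conn.close()
    return target
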