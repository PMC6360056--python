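"""Cohort identification on the star database.

A :class:`StudyDefinition` decomposes a clinical recruitment question into
panels of criteria (panels are conjoined; a panel can be an exclusion), and
each criterion belongs to one of the eight categories the mapping has to
support:

1.  SAME_EVENT      — facts collected at one and the same event
2.  NUM_CMP         — numeric value vs a fixed threshold
3.  DATE_CMP        — fact date vs a fixed date
4.  ABSENT          — the fact is not set (no observation for the concept)
5.  STR_EXACT       — exact string match
6.  STR_WILDCARD    — free-text search with wildcards
7a. TEMPORAL_SEQ    — events in temporal order
7b. TEMPORAL_GAP    — event A at least x days after event B

Concept matching is by family: a criterion concept code matches a fact
whose ``concept_cd`` equals it or extends it by a ``:``-separated suffix
(so a coded column matches all its values). A criterion may carry an
``anchor`` (concept family or nested criterion): NUM_CMP/DATE_CMP then only
consider facts at least ``gap_days`` (and at most ``gap_days_max``) days
after some anchor event — that is the 7b constraint attached to a value
check — and ABSENT means "no such fact inside the window". MOST_RECENT
aggregation restricts the check to the fact(s) on the patient's latest
qualifying date.

ABSENT is concept absence by construction: the transform emits no fact for
a null source cell, so "value is not set" and "no fact" coincide; the two
decisions must stay consistent.
"""

from __future__ import annotations

import datetime as dt
import re
import sqlite3
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .eav import concept_code
from .oracle import STUDY_PARAMS
from .star import StarDatabase

__all__ = [
    "CriterionKind",
    "Comparator",
    "Aggregation",
    "Criterion",
    "Panel",
    "StudyDefinition",
    "StudyResult",
    "UnknownConceptError",
    "eval_criterion",
    "eval_study",
    "criteria_profile",
    "bundled_study",
    "bundled_studies",
    "load_study",
]


class UnknownConceptError(KeyError):
    pass


class CriterionKind(str, Enum):
    SAME_EVENT = "SAME_EVENT"        # category 1
    NUM_CMP = "NUM_CMP"              # category 2
    DATE_CMP = "DATE_CMP"            # category 3
    ABSENT = "ABSENT"                # category 4
    STR_EXACT = "STR_EXACT"          # category 5
    STR_WILDCARD = "STR_WILDCARD"    # category 6
    TEMPORAL_SEQ = "TEMPORAL_SEQ"    # category 7a
    TEMPORAL_GAP = "TEMPORAL_GAP"    # category 7b


_KIND_LABEL = {
    CriterionKind.SAME_EVENT: "1",
    CriterionKind.NUM_CMP: "2",
    CriterionKind.DATE_CMP: "3",
    CriterionKind.ABSENT: "4",
    CriterionKind.STR_EXACT: "5",
    CriterionKind.STR_WILDCARD: "6",
    CriterionKind.TEMPORAL_SEQ: "7a",
    CriterionKind.TEMPORAL_GAP: "7b",
}


class Comparator(str, Enum):
    LT = "LT"
    LE = "LE"
    EQ = "EQ"
    GE = "GE"
    GT = "GT"

    def apply(self, series: pd.Series, threshold) -> pd.Series:
        return {
            Comparator.LT: series < threshold,
            Comparator.LE: series <= threshold,
            Comparator.EQ: series == threshold,
            Comparator.GE: series >= threshold,
            Comparator.GT: series > threshold,
        }[self]


class Aggregation(str, Enum):
    ANY = "ANY"
    MOST_RECENT = "MOST_RECENT"


@dataclass
class Criterion:
    kind: CriterionKind
    concepts: list[str]
    comparator: Optional[Comparator] = None
    threshold: Optional[object] = None  # number | ISO date | string | pattern
    gap_days: Optional[int] = None
    gap_days_max: Optional[int] = None
    anchor: Optional[Union[list[str], "Criterion"]] = None
    bound: Optional[Union[list[str], "Criterion"]] = None  # upper bound of a sequence
    events: Optional["Criterion"] = None  # nested criterion supplying the A events
    aggregation: Aggregation = Aggregation.ANY

    def __post_init__(self) -> None:
        if self.kind in (CriterionKind.NUM_CMP, CriterionKind.DATE_CMP):
            if self.comparator is None or self.threshold is None:
                raise ValueError(f"{self.kind.value} requires comparator and threshold")
        if self.kind is CriterionKind.SAME_EVENT and len(self.concepts) < 2:
            raise ValueError("SAME_EVENT requires at least two concepts")
        if self.kind is CriterionKind.TEMPORAL_GAP:
            if self.gap_days is None or self.anchor is None:
                raise ValueError("TEMPORAL_GAP requires gap_days and an anchor event")
        if self.kind is CriterionKind.TEMPORAL_SEQ and self.anchor is None:
            raise ValueError("TEMPORAL_SEQ requires an anchor event")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind.value, "concepts": list(self.concepts)}
        if self.comparator is not None:
            d["comparator"] = self.comparator.value
        if self.threshold is not None:
            d["threshold"] = self.threshold
        if self.gap_days is not None:
            d["gap_days"] = self.gap_days
        if self.gap_days_max is not None:
            d["gap_days_max"] = self.gap_days_max
        if self.anchor is not None:
            d["anchor"] = self.anchor.to_dict() if isinstance(self.anchor, Criterion) else list(self.anchor)
        if self.bound is not None:
            d["bound"] = self.bound.to_dict() if isinstance(self.bound, Criterion) else list(self.bound)
        if self.events is not None:
            d["events"] = self.events.to_dict()
        if self.aggregation is not Aggregation.ANY:
            d["aggregation"] = self.aggregation.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Criterion":
        def event(v):
            if v is None:
                return None
            return cls.from_dict(v) if isinstance(v, Mapping) else list(v)

        return cls(
            kind=CriterionKind(d["kind"]),
            concepts=list(d.get("concepts", [])),
            comparator=Comparator(d["comparator"]) if d.get("comparator") else None,
            threshold=d.get("threshold"),
            gap_days=d.get("gap_days"),
            gap_days_max=d.get("gap_days_max"),
            anchor=event(d.get("anchor")),
            bound=event(d.get("bound")),
            events=cls.from_dict(d["events"]) if d.get("events") else None,
            aggregation=Aggregation(d.get("aggregation", "ANY")),
        )


@dataclass
class Panel:
    criteria: list[Criterion]
    connector: str = "AND"  # AND | OR
    exclude: bool = False

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("panel needs at least one criterion")
        if self.connector not in ("AND", "OR"):
            raise ValueError("connector must be AND or OR")

    def to_dict(self) -> dict:
        return {
            "connector": self.connector,
            "exclude": self.exclude,
            "criteria": [c.to_dict() for c in self.criteria],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Panel":
        return cls(
            criteria=[Criterion.from_dict(c) for c in d["criteria"]],
            connector=d.get("connector", "AND"),
            exclude=bool(d.get("exclude", False)),
        )


@dataclass
class StudyDefinition:
    id: Union[int, str]
    description: str
    panels: list[Panel]

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("study needs at least one panel")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "description": self.description,
            "panels": [p.to_dict() for p in self.panels],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDefinition":
        return cls(
            id=d["id"],
            description=d.get("description", ""),
            panels=[Panel.from_dict(p) for p in d["panels"]],
        )


def load_study(path: Path | str) -> StudyDefinition:
    return StudyDefinition.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyResult:
    study_id: Union[int, str]
    patients: set[int]
    per_panel: list[tuple[bool, int]]  # (exclude flag, patient count)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "patient_count": len(self.patients),
            "patients": sorted(self.patients),
            "per_panel": [
                {"exclude": ex, "patient_count": n} for ex, n in self.per_panel
            ],
        }


# ---------------------------------------------------------------------------
# evaluation


class _Facts:
    """Cached fact/patient frames of one star database."""

    def __init__(self, star: StarDatabase):
        self.df = pd.read_sql_query(
            "SELECT encounter_num, patient_num, concept_cd, start_date, instance_num,"
            " valtype_cd, tval_char, nval_num, observation_blob"
            " FROM observation_fact WHERE upload_id = ?",
            star.conn,
            params=(star.upload_id,),
        )
        self.df["start_date"] = pd.to_datetime(self.df["start_date"])
        self.all_patients: set[int] = {
            int(r[0])
            for r in star.conn.execute(
                "SELECT patient_num FROM patient_dimension WHERE upload_id = ?",
                (star.upload_id,),
            )
        }
        self.known_codes: set[str] = {
            r[0] for r in star.conn.execute("SELECT concept_cd FROM concept_dimension")
        }

    def _known(self, code: str) -> bool:
        if any(k == code or k.startswith(code + ":") for k in self.known_codes):
            return True
        # a value-suffixed member of an observed coded-column family is a
        # legal query target even if that particular value never occurred
        # (its absence is then vacuously true)
        if ":" in code:
            parent = code.rsplit(":", 1)[0]
            return any(k.startswith(parent + ":") for k in self.known_codes)
        return False

    def family(self, codes: Sequence[str]) -> pd.DataFrame:
        for code in codes:
            if not self._known(code):
                raise UnknownConceptError(f"concept {code!r} not present in the ontology")
        mask = pd.Series(False, index=self.df.index)
        for code in codes:
            mask |= (self.df["concept_cd"] == code) | self.df["concept_cd"].str.startswith(
                code + ":"
            )
        return self.df[mask]


def _wildcard_to_regex(pattern: str) -> re.Pattern:
    # SQL LIKE semantics: % = any run, _ = any single character
    out = []
    for ch in pattern:
        if ch == "%":
            out.append(".*")
        elif ch == "_":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return re.compile("^" + "".join(out) + "$", re.IGNORECASE | re.DOTALL)


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"patient_num": pd.Series(dtype=int),
                         "start_date": pd.Series(dtype="datetime64[ns]")})


def _event_dates(facts: _Facts, spec: Union[Sequence[str], Criterion]) -> pd.DataFrame:
    """(patient_num, start_date) qualifying events for an anchor/bound spec."""
    if isinstance(spec, Criterion):
        _, events = _eval(facts, spec)
        return events
    return facts.family(list(spec))[["patient_num", "start_date"]]


def _eval(facts: _Facts, crit: Criterion) -> tuple[set[int], pd.DataFrame]:
    """Evaluate one criterion → (patients, qualifying events).

    Qualifying events are (patient_num, start_date) rows; for SAME_EVENT the
    event date is the shared test date.
    """
    kind = crit.kind

    if kind is CriterionKind.SAME_EVENT:
        frames = []
        for code in crit.concepts:
            fam = facts.family([code])[["patient_num", "encounter_num", "instance_num", "start_date"]]
            frames.append(fam.assign(_c=code))
        allf = pd.concat(frames, ignore_index=True)
        grouped = allf.groupby(["patient_num", "encounter_num", "instance_num"])["_c"].nunique()
        hits = grouped[grouped == len(crit.concepts)].reset_index()
        if hits.empty:
            return set(), _empty_events()
        ev = allf.merge(
            hits[["patient_num", "encounter_num", "instance_num"]],
            on=["patient_num", "encounter_num", "instance_num"],
        )[["patient_num", "start_date"]].drop_duplicates()
        return set(hits["patient_num"].astype(int)), ev

    if kind is CriterionKind.ABSENT:
        fam = facts.family(crit.concepts)
        if crit.anchor is not None:
            fam = _windowed(facts, crit, fam)
        present = set(fam["patient_num"].astype(int))
        patients = facts.all_patients - present
        return patients, _empty_events()

    fam = facts.family(crit.concepts) if crit.concepts else _empty_events()

    if kind in (CriterionKind.NUM_CMP, CriterionKind.DATE_CMP, CriterionKind.TEMPORAL_GAP):
        if kind is CriterionKind.NUM_CMP:
            fam = fam[fam["valtype_cd"] == "N"]
        if crit.anchor is not None:
            fam = _windowed(facts, crit, fam)
        if crit.aggregation is Aggregation.MOST_RECENT and not fam.empty:
            latest = fam.groupby("patient_num")["start_date"].transform("max")
            fam = fam[fam["start_date"] == latest]
        if kind is CriterionKind.NUM_CMP:
            ok = fam[crit.comparator.apply(fam["nval_num"], float(crit.threshold))]
        elif kind is CriterionKind.DATE_CMP:
            ok = fam[crit.comparator.apply(fam["start_date"], pd.Timestamp(str(crit.threshold)))]
        else:  # TEMPORAL_GAP without value check: windowed existence
            ok = fam
        return set(ok["patient_num"].astype(int)), ok[["patient_num", "start_date"]]

    if kind is CriterionKind.STR_EXACT:
        ok = fam[(fam["valtype_cd"] == "T") & (fam["tval_char"] == str(crit.threshold))]
        return set(ok["patient_num"].astype(int)), ok[["patient_num", "start_date"]]

    if kind is CriterionKind.STR_WILDCARD:
        rx = _wildcard_to_regex(str(crit.threshold))
        text = fam["tval_char"].fillna("") + " " + fam["observation_blob"].fillna("")
        ok = fam[text.apply(lambda s: rx.match(s) is not None)]
        return set(ok["patient_num"].astype(int)), ok[["patient_num", "start_date"]]

    if kind is CriterionKind.TEMPORAL_SEQ:
        if crit.events is not None:
            a = _event_dates(facts, crit.events)
        else:
            a = fam[["patient_num", "start_date"]]
        b = _event_dates(facts, crit.anchor)
        merged = a.merge(b, on="patient_num", suffixes=("", "_b"))
        ok = merged[merged["start_date"] > merged["start_date_b"]]
        if crit.bound is not None:
            c = _event_dates(facts, crit.bound)
            ok = ok.merge(c, on="patient_num", suffixes=("", "_c"))
            ok = ok[ok["start_date"] < ok["start_date_c"]]
        ev = ok[["patient_num", "start_date"]].drop_duplicates()
        return set(ev["patient_num"].astype(int)), ev

    raise ValueError(f"unhandled criterion kind {kind}")


def _windowed(facts: _Facts, crit: Criterion, fam: pd.DataFrame) -> pd.DataFrame:
    """Restrict facts to those within [gap_days, gap_days_max] after an anchor."""
    anchors = _event_dates(facts, crit.anchor)
    if fam.empty or anchors.empty:
        return fam.iloc[0:0]
    lo = crit.gap_days if crit.gap_days is not None else 0
    fam = fam.reset_index().rename(columns={"index": "_row"})
    merged = fam.merge(anchors, on="patient_num", suffixes=("", "_anchor"))
    diff = (merged["start_date"] - merged["start_date_anchor"]).dt.days
    ok = diff >= lo
    if crit.gap_days_max is not None:
        ok &= diff <= crit.gap_days_max
    rows = sorted(set(merged.loc[ok, "_row"]))
    return fam[fam["_row"].isin(rows)].drop(columns=["_row"]).set_index(pd.Index(rows))


def eval_criterion(star: StarDatabase, crit: Criterion) -> tuple[set[int], list]:
    """Evaluate a single criterion on a star database.

    Returns the qualifying patient set and the qualifying (patient, date)
    events.
    """
    facts = _Facts(star)
    patients, ev = _eval(facts, crit)
    events = [(int(p), d.date()) for p, d in ev.itertuples(index=False)]
    return patients, events


def eval_study(star: StarDatabase, study: StudyDefinition) -> StudyResult:
    """Evaluate a study: intersection over panels, exclusion panels subtract."""
    facts = _Facts(star)
    result: Optional[set[int]] = None
    per_panel: list[tuple[bool, int]] = []
    for panel in study.panels:
        sets = [_eval(facts, c)[0] for c in panel.criteria]
        if panel.connector == "AND":
            pset = set.intersection(*sets)
        else:
            pset = set.union(*sets)
        per_panel.append((panel.exclude, len(pset)))
        if panel.exclude:
            result = (result if result is not None else set(facts.all_patients)) - pset
        else:
            result = pset if result is None else (result & pset)
    return StudyResult(study_id=study.id, patients=result or set(), per_panel=per_panel)


def criteria_profile(study: StudyDefinition) -> set[str]:
    """Criterion-category labels exercised by a study (nested events count)."""
    labels: set[str] = set()

    def visit(crit: Criterion) -> None:
        labels.add(_KIND_LABEL[crit.kind])
        if crit.kind not in (CriterionKind.TEMPORAL_GAP, CriterionKind.TEMPORAL_SEQ):
            if crit.anchor is not None and crit.gap_days is not None:
                labels.add("7b")  # gap window attached to a value/absence check
        for sub in (crit.anchor, crit.bound, crit.events):
            if isinstance(sub, Criterion):
                visit(sub)

    for panel in study.panels:
        for crit in panel.criteria:
            visit(crit)
    return labels


# ---------------------------------------------------------------------------
# bundled studies


def bundled_study(study_id: int, prefix: str = "SRC") -> StudyDefinition:
    """The four bundled transplant cohort questions.

    1. Three specific lab analytes collected in one and the same lab test,
       with an elevated creatinine after the transplantation.
    2. Alive, HCV-positive, with a follow-up after the transplantation.
    3. Kidney (but not pancreas) transplant in the study window, graft
       rejection, and a free-text-documented urinary tract infection
       between the transplantation and the rejection.
    4. CKD-stage diagnosis, transplant in the study window, most recent
       hemoglobin collected >= 183 days post-transplant within a target
       band, no ESA treatment within six months after a transplantation,
       and most recent UACR (>= 183 days post-transplant) below a cap.
    """
    lab = lambda code: concept_code(prefix, "LabValue", code)
    tx_organ = concept_code(prefix, "Transplantation", "organ")
    diag = concept_code(prefix, "Diagnosis", "diag_code")
    exam_type = concept_code(prefix, "Examination", "exam_type")
    finding = concept_code(prefix, "Finding", "finding_text")
    drug = concept_code(prefix, "Medication", "drug_code")

    if study_id == 1:
        p = STUDY_PARAMS[1]
        a1, a2, a3 = p["analytes"]
        return StudyDefinition(
            id=1,
            description="Triple lab panel in one test, elevated creatinine, post-transplant",
            panels=[
                Panel(
                    criteria=[
                        Criterion(CriterionKind.SAME_EVENT, [lab(a1), lab(a2), lab(a3)]),
                        Criterion(
                            CriterionKind.NUM_CMP, [lab(a1)],
                            comparator=Comparator.GT, threshold=p["crea_threshold"],
                        ),
                        Criterion(CriterionKind.TEMPORAL_SEQ, [lab(a1)], anchor=[tx_organ]),
                    ]
                )
            ],
        )
    if study_id == 2:
        p = STUDY_PARAMS[2]
        return StudyDefinition(
            id=2,
            description="Alive, HCV-positive, follow-up after transplantation",
            panels=[
                Panel(
                    criteria=[
                        Criterion(
                            CriterionKind.NUM_CMP, [lab(p["hcv_analyte"])],
                            comparator=Comparator.GT, threshold=p["hcv_threshold"],
                        ),
                        Criterion(
                            CriterionKind.ABSENT,
                            [concept_code(prefix, "Diagnosis", "diag_code", p["death_code"])],
                        ),
                        Criterion(
                            CriterionKind.TEMPORAL_SEQ,
                            [concept_code(prefix, "Examination", "exam_type", p["followup_type"])],
                            anchor=[tx_organ],
                        ),
                    ]
                )
            ],
        )
    if study_id == 3:
        p = STUDY_PARAMS[3]
        return StudyDefinition(
            id=3,
            description="Kidney-not-pancreas transplant, rejection, free-text UTI between",
            panels=[
                Panel(
                    criteria=[
                        Criterion(
                            CriterionKind.STR_EXACT, [tx_organ], threshold=p["organ"],
                        ),
                        Criterion(
                            CriterionKind.DATE_CMP, [tx_organ],
                            comparator=Comparator.GE, threshold=p["window_start"],
                        ),
                        Criterion(
                            CriterionKind.TEMPORAL_SEQ,
                            [],
                            events=Criterion(
                                CriterionKind.STR_WILDCARD, [finding],
                                threshold=p["keyword_pattern"],
                            ),
                            anchor=[tx_organ],
                            bound=[concept_code(prefix, "Diagnosis", "diag_code", p["rejection_code"])],
                        ),
                    ]
                ),
                Panel(
                    exclude=True,
                    criteria=[
                        Criterion(
                            CriterionKind.STR_EXACT, [tx_organ], threshold=p["excluded_organ"],
                        )
                    ],
                ),
            ],
        )
    if study_id == 4:
        p = STUDY_PARAMS[4]
        return StudyDefinition(
            id=4,
            description="CKD stage, recent hemoglobin band, no early ESA, recent UACR cap",
            panels=[
                Panel(
                    criteria=[
                        Criterion(CriterionKind.STR_EXACT, [diag], threshold=p["ckd_code"]),
                        Criterion(
                            CriterionKind.DATE_CMP, [tx_organ],
                            comparator=Comparator.GE, threshold=p["transplant_after"],
                        ),
                        Criterion(
                            CriterionKind.NUM_CMP, [lab(p["hb_analyte"])],
                            comparator=Comparator.GE, threshold=p["hb_low"],
                            anchor=[tx_organ], gap_days=p["gap_days"],
                            aggregation=Aggregation.MOST_RECENT,
                        ),
                        Criterion(
                            CriterionKind.NUM_CMP, [lab(p["hb_analyte"])],
                            comparator=Comparator.LE, threshold=p["hb_high"],
                            anchor=[tx_organ], gap_days=p["gap_days"],
                            aggregation=Aggregation.MOST_RECENT,
                        ),
                        Criterion(
                            CriterionKind.ABSENT,
                            [concept_code(prefix, "Medication", "drug_code", p["esa_code"])],
                            anchor=[tx_organ], gap_days=0,
                            gap_days_max=p["esa_window_days"],
                        ),
                        Criterion(
                            CriterionKind.NUM_CMP, [lab(p["uacr_analyte"])],
                            comparator=Comparator.LE, threshold=p["uacr_max"],
                            anchor=[tx_organ], gap_days=p["gap_days"],
                            aggregation=Aggregation.MOST_RECENT,
                        ),
                    ]
                )
            ],
        )
    raise KeyError(f"unknown bundled study id {study_id}")


def bundled_studies(prefix: str = "SRC") -> dict[int, StudyDefinition]:
    return {i: bundled_study(i, prefix) for i in (1, 2, 3, 4)}
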