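"""Cohort data model: subjects, visits, biomarker-based diagnostic labels.

A longitudinal morphometry study is organised around *visit pairs*: two
scans of the same subject separated by an interval ``dt`` (years).  This
module holds the tabular side of that design — subjects with dated visits,
CSF amyloid-beta values, diagnostic categories derived from the amyloid
cutoff, the stable-category inclusion filter, pair enumeration, and the
``dt``-window restriction used to pick high signal-to-noise pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

#: CSF amyloid-beta cutoff for amyloid positivity, pg/mL.  Values at or
#: below the cutoff are amyloid positive.
DEFAULT_AMYLOID_CUTOFF = 192.0

#: Maximum allowed gap between a CSF draw and the matched MRI visit, days.
DEFAULT_CSF_WINDOW_DAYS = 90


class Group(str, Enum):
    """Diagnostic category.

    ``Ctrl``
        cognitively unimpaired, amyloid negative.
    ``PreAD``
        cognitively unimpaired, amyloid positive (preclinical AD).
    ``MCI_AD``
        cognitively impaired (MCI or AD dementia), amyloid positive.
    """

    Ctrl = "Ctrl"
    PreAD = "PreAD"
    MCI_AD = "MCI_AD"


class CognitiveStatus(str, Enum):
    normal = "normal"
    impaired = "impaired"


class AmyloidDiscordanceError(ValueError):
    """Cognitively impaired subject with normal amyloid.

    Such subjects are presumed to harbour non-AD pathological change and
    are excluded from the study rather than assigned a category.
    """


class PairEnumerationError(ValueError):
    """A subject does not have enough visits to form a pair."""


@dataclass(frozen=True)
class Visit:
    """One imaging visit, optionally with a matched CSF measurement."""

    visit_id: str
    age: float               # years at the visit
    date: _date
    scan_ref: Optional[str] = None
    csf_abeta: Optional[float] = None   # pg/mL
    csf_date: Optional[_date] = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"visit {self.visit_id}: age must be > 0, got {self.age}")
        if self.csf_abeta is not None and not self.csf_abeta > 0:
            raise ValueError(
                f"visit {self.visit_id}: csf_abeta must be > 0, got {self.csf_abeta}"
            )

    def csf_within_window(self, max_days: int = DEFAULT_CSF_WINDOW_DAYS) -> bool:
        """Whether the CSF draw date is within ``max_days`` of the scan.

        Visits without a recorded CSF draw date are taken to be matched
        (the tolerance check only applies when both dates are known).
        """
        if self.csf_date is None:
            return True
        return abs(self.csf_date - self.date) <= timedelta(days=max_days)


@dataclass(frozen=True)
class SubjectRecord:
    """A subject with two or more longitudinal visits, sorted by date."""

    subject_id: str
    sex: str                 # "F" or "M"
    group: Group
    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if len(self.visits) < 2:
            raise ValueError(
                f"subject {self.subject_id}: needs >= 2 visits, got {len(self.visits)}"
            )
        dates = [v.date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"subject {self.subject_id}: visit dates must be strictly increasing"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class VisitPair:
    """A (reference, follow-up) scan pair of one subject.

    ``dt`` is the interval in years between the two visits and
    ``mean_age`` the arithmetic mean of the two visit ages — the age used
    when regressing change maps on age.
    """

    subject_id: str
    reference: Visit
    followup: Visit
    dt: float
    mean_age: float

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.followup.date <= self.reference.date:
            raise ValueError("followup must postdate reference")
        expected = 0.5 * (self.reference.age + self.followup.age)
        if abs(self.mean_age - expected) > 1e-9:
            raise ValueError("mean_age must equal the mean of the visit ages")

    @classmethod
    def from_visits(cls, subject_id: str, reference: Visit, followup: Visit) -> "VisitPair":
        return cls(
            subject_id=subject_id,
            reference=reference,
            followup=followup,
            dt=followup.age - reference.age,
            mean_age=0.5 * (reference.age + followup.age),
        )


@dataclass
class CohortTable:
    """The sample frame: all subjects entering the analysis."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""
    amyloid_cutoff: float = DEFAULT_AMYLOID_CUTOFF

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = [k for k, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate subject_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def group_counts(self) -> Counter:
        return Counter(s.group for s in self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass(frozen=True)
class StableFilterResult:
    """Outcome of the stable-category filter."""

    cohort: CohortTable
    n_excluded: int
    #: Counter of (first label, discordant label) transitions among excluded
    #: subjects, e.g. {(Ctrl, PreAD): 13}.
    transitions: Counter


def assign_diagnostic_category(
    cognitive_status: CognitiveStatus | str,
    csf_abeta: float,
    cutoff: float = DEFAULT_AMYLOID_CUTOFF,
) -> Group:
    """Assign Ctrl / PreAD / MCI_AD from cognition and CSF amyloid-beta.

    Cognitively normal subjects are Ctrl when CSF amyloid-beta is above the
    cutoff and PreAD when at or below it.  Cognitively impaired subjects
    must be amyloid positive (at or below the cutoff) to be labelled
    MCI_AD; impaired subjects with normal amyloid are rejected with
    :class:`AmyloidDiscordanceError`, as their impairment is presumed to
    reflect non-AD pathological change.
    """
    if not csf_abeta > 0:
        raise ValueError(f"csf_abeta must be > 0, got {csf_abeta}")
    if not cutoff > 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    status = CognitiveStatus(cognitive_status)
    amyloid_positive = csf_abeta <= cutoff
    if status is CognitiveStatus.normal:
        return Group.PreAD if amyloid_positive else Group.Ctrl
    if not amyloid_positive:
        raise AmyloidDiscordanceError(
            "cognitively impaired subject with CSF amyloid-beta above the "
            f"cutoff ({csf_abeta} > {cutoff} pg/mL): suspected non-AD "
            "pathological change, excluded"
        )
    return Group.MCI_AD


def filter_stable_subjects(
    cohort: CohortTable,
    per_visit_labels: Mapping[tuple[str, str], Group | str],
) -> StableFilterResult:
    """Keep only subjects whose diagnostic label is identical at all visits.

    ``per_visit_labels`` maps ``(subject_id, visit_id)`` to the label at
    that visit; every visit of every subject must be covered.  Converters
    are excluded and tallied by (first label, first discordant label)
    transition.
    """
    kept: list[SubjectRecord] = []
    transitions: Counter = Counter()
    for subj in cohort.subjects:
        labels = []
        for v in subj.visits:
            key = (subj.subject_id, v.visit_id)
            if key not in per_visit_labels:
                raise KeyError(f"missing per-visit label for {key}")
            labels.append(Group(per_visit_labels[key]))
        first = labels[0]
        discordant = next((lab for lab in labels[1:] if lab != first), None)
        if discordant is None:
            kept.append(subj)
        else:
            transitions[(first, discordant)] += 1
    filtered = CohortTable(
        subjects=kept,
        provenance=cohort.provenance,
        amyloid_cutoff=cohort.amyloid_cutoff,
    )
    return StableFilterResult(
        cohort=filtered, n_excluded=len(cohort) - len(kept), transitions=transitions
    )


def enumerate_visit_pairs(
    subject: SubjectRecord, mode: str = "consecutive"
) -> list[VisitPair]:
    """Enumerate (reference, follow-up) pairs for one subject.

    Modes: ``consecutive`` (n-1 pairs of adjacent visits, the default),
    ``all_pairs`` (all n·(n-1)/2 ordered combinations), and
    ``baseline_anchored`` (first visit against each later one).
    """
    visits = subject.visits
    if len(visits) < 2:
        raise PairEnumerationError(
            f"subject {subject.subject_id} has {len(visits)} visit(s); need >= 2"
        )
    sid = subject.subject_id
    if mode == "consecutive":
        combos = list(zip(visits, visits[1:]))
    elif mode == "all_pairs":
        combos = [
            (visits[i], visits[j])
            for i in range(len(visits))
            for j in range(i + 1, len(visits))
        ]
    elif mode == "baseline_anchored":
        combos = [(visits[0], v) for v in visits[1:]]
    else:
        raise ValueError(f"unknown pair enumeration mode: {mode!r}")
    return [VisitPair.from_visits(sid, a, b) for a, b in combos]


def filter_pairs_by_dt(
    pairs: Sequence[VisitPair],
    dt_min: float,
    dt_max: float = math.inf,
) -> list[VisitPair]:
    """Keep pairs with ``dt_min < dt < dt_max`` (open interval), in order."""
    if not dt_min < dt_max:
        raise ValueError(f"dt_min ({dt_min}) must be < dt_max ({dt_max})")
    return [p for p in pairs if dt_min < p.dt < dt_max]


# ---------------------------------------------------------------------------
# CSV interchange: one row per visit.

COHORT_CSV_COLUMNS = [
    "subject_id",
    "sex",
    "group",
    "visit_id",
    "date",
    "age_years",
    "csf_abeta_pgml",
    "scan_ref",
]


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        for v in s.visits:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "sex": s.sex,
                    "group": s.group.value,
                    "visit_id": v.visit_id,
                    "date": v.date.isoformat(),
                    "age_years": v.age,
                    "csf_abeta_pgml": "" if v.csf_abeta is None else v.csf_abeta,
                    "scan_ref": "" if v.scan_ref is None else v.scan_ref,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
    amyloid_cutoff: float = DEFAULT_AMYLOID_CUTOFF,
    provenance: str = "",
) -> CohortTable:
    """Read a one-row-per-visit cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(
        path, dtype={"subject_id": str, "visit_id": str}, float_precision="round_trip"
    )
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path}: missing columns {sorted(missing)}")
    subjects = []
    for sid, rows in df.groupby("subject_id", sort=False):
        rows = rows.sort_values("date")
        visits = tuple(
            Visit(
                visit_id=str(r.visit_id),
                age=float(r.age_years),
                date=_date.fromisoformat(str(r.date)),
                csf_abeta=None if pd.isna(r.csf_abeta_pgml) else float(r.csf_abeta_pgml),
                scan_ref=None if pd.isna(r.scan_ref) else str(r.scan_ref),
            )
            for r in rows.itertuples()
        )
        groups = set(rows["group"])
        if len(groups) != 1:
            raise ValueError(f"subject {sid}: inconsistent group labels {groups}")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                sex=str(rows["sex"].iloc[0]),
                group=Group(groups.pop()),
                visits=visits,
            )
        )
    return CohortTable(subjects=subjects, provenance=provenance, amyloid_cutoff=amyloid_cutoff)
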