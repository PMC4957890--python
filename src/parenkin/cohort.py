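"""Matched case-control cohort containers and 1:1 matching.

A cohort is a list of matched pairs; each subject record carries the
matching covariates (age, MRI year), the adjustment covariates (menopausal
status, family history, mammographic density category) and a dictionary of
breast-wise imaging measures.  Matching follows the study design: one
control per case, within +/-3 years of age and +/-1 year of MRI date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "MatchedPair",
    "MatchedCohort",
    "MatchingError",
    "greedy_match",
    "AGE_TOLERANCE_YEARS",
    "YEAR_TOLERANCE",
]

AGE_TOLERANCE_YEARS = 3.0
YEAR_TOLERANCE = 1

_RESERVED_COLUMNS = (
    "subject_id",
    "pair_id",
    "group",
    "is_case",
    "age",
    "mri_year",
    "menopausal",
    "family_history",
    "density",
)


class MatchingError(ValueError):
    """Raised when 1:1 matching is infeasible under the tolerances."""

    def __init__(self, unmatched: list[str]):
        self.unmatched = list(unmatched)
        super().__init__(
            "matching infeasible under tolerances; unmatched cases: "
            + ", ".join(self.unmatched)
        )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "case" or "control"
    age: float
    mri_year: int
    menopausal: int  # 1 = postmenopausal
    family_history: int  # 1 = positive
    density: int  # ordinal BI-RADS density category 1..4
    measures: dict[str, float] = field(default_factory=dict)

    def covariate(self, name: str) -> float:
        """Look up a covariate by name, searching fields then measures."""
        if name in ("age", "mri_year", "menopausal", "family_history", "density"):
            return float(getattr(self, name))
        if name in self.measures:
            return float(self.measures[name])
        raise KeyError(f"unknown covariate {name!r} for subject {self.subject_id}")


@dataclass
class MatchedPair:
    case: SubjectRecord
    control: SubjectRecord

    @property
    def age_difference(self) -> float:
        return self.case.age - self.control.age

    @property
    def year_difference(self) -> int:
        return int(self.case.mri_year - self.control.mri_year)


@dataclass
class MatchedCohort:
    pairs: list[MatchedPair]
    age_tolerance: float = AGE_TOLERANCE_YEARS
    year_tolerance: int = YEAR_TOLERANCE
    # generator provenance (generative parameters, optional images); not serialized
    metadata: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate(self) -> None:
        for p in self.pairs:
            if p.case.group != "case" or p.control.group != "control":
                raise ValueError("each pair must hold one case and one control")
            if abs(p.age_difference) > self.age_tolerance:
                raise ValueError(
                    f"pair ({p.case.subject_id}, {p.control.subject_id}) violates the "
                    f"age tolerance of +/-{self.age_tolerance} years"
                )
            if abs(p.year_difference) > self.year_tolerance:
                raise ValueError(
                    f"pair ({p.case.subject_id}, {p.control.subject_id}) violates the "
                    f"MRI-year tolerance of +/-{self.year_tolerance}"
                )

    def measure_names(self) -> list[str]:
        names: list[str] = []
        for p in self.pairs:
            for key in p.case.measures:
                if key not in names:
                    names.append(key)
        return names

    def to_subject_frame(self) -> pd.DataFrame:
        """One row per subject with covariates, measures, pair id and label."""
        rows = []
        for i, p in enumerate(self.pairs):
            for rec in (p.case, p.control):
                row = {
                    "subject_id": rec.subject_id,
                    "pair_id": i,
                    "group": rec.group,
                    "is_case": int(rec.group == "case"),
                    "age": rec.age,
                    "mri_year": rec.mri_year,
                    "menopausal": rec.menopausal,
                    "family_history": rec.family_history,
                    "density": rec.density,
                }
                row.update(rec.measures)
                rows.append(row)
        return pd.DataFrame(rows)

    def diff_matrix(self, covariates: list[str]) -> np.ndarray:
        """Within-pair differences (case minus control), shape (n_pairs, p)."""
        out = np.empty((self.n_pairs, len(covariates)))
        for i, p in enumerate(self.pairs):
            for j, name in enumerate(covariates):
                out[i, j] = p.case.covariate(name) - p.control.covariate(name)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_subject_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "MatchedCohort":
        return cls.from_subject_frame(pd.read_csv(path), **kwargs)

    @classmethod
    def from_subject_frame(
        cls,
        frame: pd.DataFrame,
        age_tolerance: float = AGE_TOLERANCE_YEARS,
        year_tolerance: int = YEAR_TOLERANCE,
    ) -> "MatchedCohort":
        measure_cols = [c for c in frame.columns if c not in _RESERVED_COLUMNS]
        pairs = []
        for pair_id, grp in frame.groupby("pair_id", sort=True):
            recs = {}
            for _, row in grp.iterrows():
                rec = SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    mri_year=int(row["mri_year"]),
                    menopausal=int(row["menopausal"]),
                    family_history=int(row["family_history"]),
                    density=int(row["density"]),
                    measures={c: float(row[c]) for c in measure_cols},
                )
                recs[rec.group] = rec
            if set(recs) != {"case", "control"}:
                raise ValueError(f"pair {pair_id} must hold one case and one control")
            pairs.append(MatchedPair(case=recs["case"], control=recs["control"]))
        cohort = cls(pairs, age_tolerance=age_tolerance, year_tolerance=year_tolerance)
        cohort.validate()
        return cohort


def _assignment_match(
    cases: list[SubjectRecord],
    controls: list[SubjectRecord],
    age_tolerance: float,
    year_tolerance: int,
) -> tuple[list[MatchedPair], list[str]]:
    """Optimal 1:1 assignment minimising total |age difference|.

    Ineligible case-control combinations carry a prohibitive cost; any case
    whose assigned control is ineligible is reported unmatched.
    """
    from scipy.optimize import linear_sum_assignment

    cases = sorted(cases, key=lambda r: (r.age, r.subject_id))
    controls = sorted(controls, key=lambda r: (r.age, r.subject_id))
    big = 1e6
    cost = np.full((len(cases), len(controls)), big)
    for i, ca in enumerate(cases):
        for j, co in enumerate(controls):
            if (
                abs(ca.age - co.age) <= age_tolerance
                and abs(ca.mri_year - co.mri_year) <= year_tolerance
            ):
                cost[i, j] = abs(ca.age - co.age)
    rows, cols = linear_sum_assignment(cost)
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for i, j in zip(rows, cols):
        if cost[i, j] >= big:
            unmatched.append(cases[i].subject_id)
        else:
            pairs.append(MatchedPair(case=cases[i], control=controls[j]))
    return pairs, unmatched


def greedy_match(
    cases: list[SubjectRecord],
    controls: list[SubjectRecord],
    age_tolerance: float = AGE_TOLERANCE_YEARS,
    year_tolerance: int = YEAR_TOLERANCE,
) -> MatchedCohort:
    """1:1 nearest-age matching under age and MRI-year tolerances.

    Cases are processed in order of increasing age; each takes the eligible
    remaining control with the smallest absolute age difference (ties broken
    by year difference, then subject id).  Because this heuristic can strand
    a case for which a feasible assignment exists, an optimal rescue pass
    (minimum-cost bipartite assignment on age difference, ineligible pairs
    excluded) is attempted before failure is declared.  Deterministic.
    Raises :class:`MatchingError` listing every case left unmatched.
    """
    remaining = list(controls)
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for case in sorted(cases, key=lambda r: (r.age, r.subject_id)):
        eligible = [
            c
            for c in remaining
            if abs(case.age - c.age) <= age_tolerance
            and abs(case.mri_year - c.mri_year) <= year_tolerance
        ]
        if not eligible:
            unmatched.append(case.subject_id)
            continue
        best = min(
            eligible,
            key=lambda c: (
                abs(case.age - c.age),
                abs(case.mri_year - c.mri_year),
                c.subject_id,
            ),
        )
        remaining.remove(best)
        pairs.append(MatchedPair(case=case, control=best))
    if unmatched:
        pairs, unmatched = _assignment_match(
            cases, controls, age_tolerance, year_tolerance
        )
    if unmatched:
        raise MatchingError(unmatched)
    cohort = MatchedCohort(pairs, age_tolerance=age_tolerance, year_tolerance=year_tolerance)
    cohort.validate()
    return cohort
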