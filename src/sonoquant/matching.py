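"""Nearest-neighbour selection of matched external controls.

Each study subject is matched to the k candidates (default 5) from an
external pool — e.g. an ADNI-style longitudinal cohort — that are closest
in age among those with the same gender and an MMSE within 2 points.
Ties in age distance are broken by smaller MMSE gap, then lexicographic
candidate id, which makes the selection fully deterministic and
order-independent.  Diagnosis (MCI/AD) can additionally be required to
match exactly.

Matching is with replacement across cases by default (a control may
serve several cases); a greedy without-replacement variant processes
cases in id order and removes each selected control from the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError

#: Default number of controls per case and MMSE tolerance.
K_CONTROLS = 5
MMSE_TOLERANCE = 2


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    age: float
    gender: str  # F | M
    mmse: int
    diagnosis: str = ""  # MCI | AD | ""

    def __post_init__(self) -> None:
        if not 0 <= self.mmse <= 30:
            raise ParameterError(f"MMSE {self.mmse} outside 0..30")
        if self.gender not in ("F", "M"):
            raise ParameterError(f"gender must be F or M, got {self.gender!r}")


@dataclass
class MatchResult:
    case_id: str
    control_ids: list = field(default_factory=list)
    age_gaps: list = field(default_factory=list)
    mmse_gaps: list = field(default_factory=list)
    shortfall: bool = False


def _sort_key(index: SubjectRecord):
    def key(c: SubjectRecord):
        return (abs(c.age - index.age), abs(c.mmse - index.mmse), c.id)

    return key


def match_controls(
    index: SubjectRecord,
    pool: list[SubjectRecord],
    k: int = K_CONTROLS,
    mmse_tol: int = MMSE_TOLERANCE,
    match_diagnosis: bool = False,
) -> MatchResult:
    """The k eligible pool members closest in age to the index subject.

    Eligibility: same gender, |MMSE gap| <= ``mmse_tol``, and (optionally)
    identical diagnosis.  Fewer than k eligible candidates sets the
    shortfall flag; an empty eligible set yields an empty match list.
    """
    if not pool:
        raise ParameterError("candidate pool is empty")
    if k < 1:
        raise ParameterError("k must be >= 1")
    eligible = [
        c
        for c in pool
        if c.gender == index.gender
        and abs(c.mmse - index.mmse) <= mmse_tol
        and (not match_diagnosis or c.diagnosis == index.diagnosis)
    ]
    eligible.sort(key=_sort_key(index))
    chosen = eligible[:k]
    return MatchResult(
        case_id=index.id,
        control_ids=[c.id for c in chosen],
        age_gaps=[abs(c.age - index.age) for c in chosen],
        mmse_gaps=[abs(c.mmse - index.mmse) for c in chosen],
        shortfall=len(eligible) < k,
    )


def match_cohort(
    cases: list[SubjectRecord],
    pool: list[SubjectRecord],
    k: int = K_CONTROLS,
    mmse_tol: int = MMSE_TOLERANCE,
    match_diagnosis: bool = False,
    with_replacement: bool = True,
) -> list[MatchResult]:
    """Match every case independently (default) or greedily without reuse.

    Without replacement, cases are processed in lexicographic id order and
    each selected control is removed from the pool for later cases.
    """
    if with_replacement:
        return [
            match_controls(case, pool, k, mmse_tol, match_diagnosis) for case in cases
        ]
    remaining = {c.id: c for c in pool}
    results = {}
    for case in sorted(cases, key=lambda c: c.id):
        res = match_controls(case, list(remaining.values()), k, mmse_tol, match_diagnosis)
        for cid in res.control_ids:
            del remaining[cid]
        results[case.id] = res
    return [results[c.id] for c in cases]


def records_from_table(table: pd.DataFrame) -> list[SubjectRecord]:
    """SubjectRecords from a (id, age, gender, mmse[, diagnosis]) table."""
    return [
        SubjectRecord(
            id=str(row["id"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            mmse=int(row["mmse"]),
            diagnosis=str(row.get("diagnosis", "")),
        )
        for _, row in table.iterrows()
    ]


def matches_to_table(results: list[MatchResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for rank, (cid, ag, mg) in enumerate(
            zip(res.control_ids, res.age_gaps, res.mmse_gaps), start=1
        ):
            rows.append(
                {"case_id": res.case_id, "control_id": cid, "age_gap": ag,
                 "mmse_gap": mg, "rank": rank}
            )
    return pd.DataFrame(rows, columns=["case_id", "control_id", "age_gap", "mmse_gap", "rank"])
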