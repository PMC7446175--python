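"""Domain types, validation, I/O and descriptive summaries for PEDIS-coded DFU cohorts.

The PEDIS system (IWGDF) grades a diabetic foot ulcer on five ordinal risk
factors — Perfusion (1–3), Extent (1–3), Depth (1–3), Infection (1–4) and
Sensation (1–2) — so the sum score ranges from 5 to 15. A cohort couples these
baseline grades with two nested six-month outcomes: any lower-extremity
amputation and major (above-ankle) amputation, coded from ICD-9-CM procedure
codes.
"""

from __future__ import annotations

import dataclasses
import math
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRADE_RANGES",
    "PEDIS_FACTORS",
    "PedisRecord",
    "Cohort",
    "OutcomeCodeMap",
    "PAPER_CODE_MAP",
    "STANDARD_SEMANTICS_MAP",
    "ValidationError",
    "validate_record",
    "pedis_sum",
    "select_index_ulcer",
    "classify_outcome",
    "descriptive_summary",
    "mean_pedis_from_marginals",
    "read_cohort",
    "write_cohort",
]

#: PEDIS factors in canonical order.
PEDIS_FACTORS = ("perfusion", "extent", "depth", "infection", "sensation")

#: Inclusive grade range per factor. Infection is the only four-level factor
#: (grade 4 = systemic inflammatory response syndrome); sensation is binary
#: (protective sensation present / lost).
GRADE_RANGES = {
    "perfusion": (1, 3),
    "extent": (1, 3),
    "depth": (1, 3),
    "infection": (1, 4),
    "sensation": (1, 2),
}

CSV_COLUMNS = (
    "patient_id",
    "age",
    "gender",
    "perfusion",
    "extent",
    "depth",
    "infection",
    "sensation",
    "outcome_any",
    "outcome_major",
    "lost_to_followup",
)


class ValidationError(ValueError):
    """Raised when a record or cohort violates the PEDIS domain constraints."""


@dataclass(frozen=True)
class PedisRecord:
    """One patient: demographics, the five PEDIS grades and six-month outcomes.

    ``outcome_major == 1`` implies ``outcome_any == 1`` (major amputations are a
    subset of any amputation). A patient lost to follow-up carries no outcomes
    and is excluded from model fitting but kept in files.
    """

    patient_id: str
    age: float
    gender: str  # "female" | "male"
    perfusion: int
    extent: int
    depth: int
    infection: int
    sensation: int
    outcome_any: int | None
    outcome_major: int | None
    lost_to_followup: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age)):
            raise ValidationError(f"age must be a finite number, got {self.age!r}")
        if self.age < 18:
            raise ValidationError(f"age must be >= 18 (adult cohort), got {self.age}")
        if self.gender not in ("female", "male"):
            raise ValidationError(f"gender must be 'female' or 'male', got {self.gender!r}")
        for factor in PEDIS_FACTORS:
            value = getattr(self, factor)
            lo, hi = GRADE_RANGES[factor]
            if not isinstance(value, int) or not lo <= value <= hi:
                raise ValidationError(
                    f"{factor} grade must be an integer in [{lo}, {hi}], got {value!r}"
                )
        if self.lost_to_followup:
            if self.outcome_any is not None or self.outcome_major is not None:
                raise ValidationError(
                    f"patient {self.patient_id}: lost to follow-up, outcomes must be missing"
                )
        else:
            for name in ("outcome_any", "outcome_major"):
                value = getattr(self, name)
                if value not in (0, 1):
                    raise ValidationError(
                        f"patient {self.patient_id}: {name} must be 0/1 "
                        f"(got {value!r}) unless lost_to_followup is set"
                    )
            if self.outcome_major == 1 and self.outcome_any != 1:
                raise ValidationError(
                    f"patient {self.patient_id}: major amputation implies any amputation"
                )


def validate_record(raw_row: Mapping[str, object]) -> PedisRecord:
    """Coerce a raw field map (e.g. a CSV row) into a range-checked PedisRecord.

    Grade fields are coerced to integers; outcomes may be missing only when the
    ``lost_to_followup`` flag is set.
    """
    row = dict(raw_row)

    def _grade(name: str) -> int:
        value = row.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValidationError(f"missing required field {name!r}")
        try:
            as_float = float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"{name} grade not numeric: {value!r}") from None
        as_int = int(round(as_float))
        if as_int != as_float:
            raise ValidationError(f"{name} grade not an integer: {value!r}")
        return as_int

    def _outcome(name: str) -> int | None:
        value = row.get(name)
        if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
            return None
        return _grade(name)

    lost = row.get("lost_to_followup", False)
    if isinstance(lost, str):
        lost = lost.strip().lower() in ("1", "true", "yes")
    else:
        lost = bool(int(lost)) if not isinstance(lost, bool) else lost

    missing = [k for k in ("patient_id", "age", "gender") if k not in row]
    if missing:
        raise ValidationError(f"missing required fields: {missing}")

    gender = str(row["gender"]).strip().lower()
    return PedisRecord(
        patient_id=str(row["patient_id"]),
        age=float(row["age"]),
        gender=gender,
        perfusion=_grade("perfusion"),
        extent=_grade("extent"),
        depth=_grade("depth"),
        infection=_grade("infection"),
        sensation=_grade("sensation"),
        outcome_any=None if lost else _outcome("outcome_any"),
        outcome_major=None if lost else _outcome("outcome_major"),
        lost_to_followup=lost,
    )


def pedis_sum(record: PedisRecord) -> int:
    """PEDIS sum score: perfusion + extent + depth + infection + sensation ∈ [5, 15]."""
    return sum(getattr(record, factor) for factor in PEDIS_FACTORS)


def select_index_ulcer(ulcers: Sequence[PedisRecord]) -> PedisRecord:
    """Pick the index ulcer for a patient with several: the one with the highest
    PEDIS sum score, ties broken by first occurrence in input order."""
    if not ulcers:
        raise ValidationError("select_index_ulcer requires a non-empty ulcer list")
    ids = {u.patient_id for u in ulcers}
    if len(ids) != 1:
        raise ValidationError(f"ulcers belong to multiple patients: {sorted(ids)}")
    best = ulcers[0]
    for ulcer in ulcers[1:]:
        if pedis_sum(ulcer) > pedis_sum(best):
            best = ulcer
    return best


# ---------------------------------------------------------------------------
# Outcome coding from ICD-9-CM procedure codes
# ---------------------------------------------------------------------------

_CODE_RE = re.compile(r"^84\.(\d{2})$")


@dataclass(frozen=True)
class OutcomeCodeMap:
    """ICD-9-CM code ranges defining the two amputation outcomes.

    Ranges are inclusive pairs of codes within the 84.xx amputation chapter.
    ``major_codes`` must be a subset of ``any_codes``.
    """

    any_codes: tuple[tuple[str, str], ...]
    major_codes: tuple[tuple[str, str], ...]
    exclude_lesser_toes: bool = False

    def __post_init__(self) -> None:
        for lo, hi in self.any_codes + self.major_codes:
            if _parse_code(lo) > _parse_code(hi):
                raise ValidationError(f"inverted code range {lo}-{hi}")
        for lo, hi in self.major_codes:
            if not any(
                _parse_code(alo) <= _parse_code(lo) and _parse_code(hi) <= _parse_code(ahi)
                for alo, ahi in self.any_codes
            ):
                raise ValidationError("major_codes must be contained in any_codes")


def _parse_code(code: str) -> int:
    m = _CODE_RE.match(code.strip())
    if not m:
        raise ValidationError(f"unparseable ICD-9-CM amputation code: {code!r}")
    return int(m.group(1))


#: The source study's stated ranges, verbatim: any amputation = 84.11–84.19,
#: major amputation = 84.11–84.12 described as "above the ankle". Note this is
#: inverted relative to standard ICD-9-CM semantics (84.11 = toe amputation);
#: it is kept as the default because it is what the study states.
PAPER_CODE_MAP = OutcomeCodeMap(
    any_codes=(("84.11", "84.19"),),
    major_codes=(("84.11", "84.12"),),
)

#: Standard ICD-9-CM semantics: 84.11 toe ... 84.15 below-knee, 84.17
#: above-knee; major (above-ankle) amputations are 84.13–84.19 here we take
#: 84.15–84.19 (disarticulations of ankle and above).
STANDARD_SEMANTICS_MAP = OutcomeCodeMap(
    any_codes=(("84.11", "84.19"),),
    major_codes=(("84.15", "84.19"),),
    exclude_lesser_toes=True,
)


def classify_outcome(
    procedure_codes: Iterable[str], code_map: OutcomeCodeMap = PAPER_CODE_MAP
) -> tuple[int, int]:
    """Map a patient's ICD-9-CM procedure codes to (outcome_any, outcome_major).

    A toe-amputation code (84.11) is ignored entirely when the map sets
    ``exclude_lesser_toes``.
    """
    values = [_parse_code(c) for c in procedure_codes]
    if code_map.exclude_lesser_toes:
        values = [v for v in values if v != 11]

    def _hit(ranges: tuple[tuple[str, str], ...]) -> int:
        return int(
            any(_parse_code(lo) <= v <= _parse_code(hi) for v in values for lo, hi in ranges)
        )

    return _hit(code_map.any_codes), _hit(code_map.major_codes)


# ---------------------------------------------------------------------------
# Cohort container and I/O
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """An ordered collection of PEDIS records with provenance metadata."""

    records: list[PedisRecord]
    provenance: str = "observed"  # "observed" | "synthetic"
    label: str = ""
    config: Mapping[str, object] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id in cohort: {dupes}")
        if self.provenance not in ("observed", "synthetic"):
            raise ValidationError(f"provenance must be observed|synthetic, got {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.records)

    def fit_eligible(self) -> "Cohort":
        """The sub-cohort usable for model fitting: not lost to follow-up."""
        return Cohort(
            [r for r in self.records if not r.lost_to_followup],
            provenance=self.provenance,
            label=self.label,
            config=self.config,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        df["lost_to_followup"] = df["lost_to_followup"].astype(int)
        for col in ("outcome_any", "outcome_major"):
            df[col] = df[col].astype("Int64")
        return df


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (missing outcomes as empty cells). Deterministic:
    identical cohorts produce byte-identical files."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path, provenance: str = "observed", label: str = "") -> Cohort:
    """Read and validate a cohort CSV; raises on missing columns or duplicate ids."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns: {missing}")
    records = [validate_record(row) for row in df.to_dict("records")]
    return Cohort(records, provenance=provenance, label=label)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

_GROUPS = (
    "overall",
    "any_nonamputee",
    "any_amputee",
    "major_nonamputee",
    "major_amputee",
)


def _group_members(records: Sequence[PedisRecord], group: str) -> list[PedisRecord]:
    if group == "overall":
        return list(records)
    outcome, status = group.split("_")
    attr = f"outcome_{outcome}"
    want = 1 if status == "amputee" else 0
    return [r for r in records if getattr(r, attr) == want]


def descriptive_summary(cohort: Cohort) -> pd.DataFrame:
    """Tidy descriptive table over the fit-eligible records.

    One row per (group, characteristic, level) with columns ``count``,
    ``percent``, ``mean`` and ``sd``. Groups are the overall sample and the
    non-amputee/amputee splits for each outcome. Subgroup percentages are
    relative to the total analysed N (so e.g. the amputee stage percentages sum
    to the amputee share of the cohort, not to 100) — the convention of the
    published descriptive table.
    """
    records = cohort.fit_eligible().records
    if not records:
        raise ValidationError("descriptive_summary requires a non-empty cohort")
    n_total = len(records)
    rows: list[dict[str, object]] = []
    for group in _GROUPS:
        members = _group_members(records, group)
        n = len(members)
        rows.append(
            dict(group=group, characteristic="n", level="", count=n,
                 percent=100.0 * n / n_total, mean=np.nan, sd=np.nan)
        )
        for gender in ("female", "male"):
            k = sum(1 for r in members if r.gender == gender)
            rows.append(
                dict(group=group, characteristic="gender", level=gender, count=k,
                     percent=100.0 * k / n_total, mean=np.nan, sd=np.nan)
            )
        for name, values in (
            ("age", [r.age for r in members]),
            ("pedis_sum", [pedis_sum(r) for r in members]),
        ):
            arr = np.asarray(values, dtype=float)
            mean = float(arr.mean()) if n else np.nan
            sd = float(arr.std(ddof=1)) if n > 1 else 0.0
            rows.append(
                dict(group=group, characteristic=name, level="", count=n,
                     percent=np.nan, mean=mean, sd=sd)
            )
        for factor in PEDIS_FACTORS:
            lo, hi = GRADE_RANGES[factor]
            for grade in range(lo, hi + 1):
                k = sum(1 for r in members if getattr(r, factor) == grade)
                rows.append(
                    dict(group=group, characteristic=factor, level=f"stage_{grade}",
                         count=k, percent=100.0 * k / n_total, mean=np.nan, sd=np.nan)
                )
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> str:
    """Aligned-text rendering of a descriptive summary table."""
    wide = summary.copy()
    wide["cell"] = np.where(
        wide["mean"].notna(),
        wide.apply(lambda r: f"{r['mean']:.2f} (SD {r['sd']:.1f})", axis=1),
        wide.apply(lambda r: f"{int(r['count'])} ({r['percent']:.1f}%)", axis=1),
    )
    pivot = wide.pivot_table(
        index=["characteristic", "level"], columns="group", values="cell", aggfunc="first"
    )[list(_GROUPS)]
    return pivot.to_string()


def mean_pedis_from_marginals(stage_counts: Mapping[str, Sequence[int]], n: int) -> float:
    """Mean PEDIS sum score implied by per-factor marginal stage counts.

    By linearity of expectation the mean of the sum score equals the sum over
    factors of the count-weighted mean grade, so the mean is recoverable from
    published marginals alone (the joint distribution is not needed).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    total = 0.0
    for factor, counts in stage_counts.items():
        if sum(counts) != n:
            raise ValidationError(f"{factor} marginal counts sum to {sum(counts)}, expected {n}")
        total += sum(grade * c for grade, c in enumerate(counts, start=1)) / n
    return total
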