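"""Cohort data model and CSV interchange.

A cohort pairs enrolled subjects (diagnosis group, AJCC stage for colorectal
cancer cases, demographics, tumor descriptors) with their qPCR reactions.
Each plasma specimen is run in three qPCR replicates and each leukocyte
specimen in a single reaction; every reaction carries Ct values for the
internal control ACTB and the two methylation targets mSEPT9 and mSDC2.
Undetected amplification is represented as ``None`` in memory and as the
literal ``ND`` (or an empty cell, on read) in CSV.

The CSV dialect is fixed: UTF-8, comma separator, ``.`` decimal, required
header, one reaction per row, subject metadata repeated on every row.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

GROUPS = ("CRC", "Ade", "HP", "OtherTumor", "Control")
AJCC_STAGES = ("0", "I", "II", "III", "IV", "unknown")
EARLY_STAGES = ("0", "I", "II")
T_STAGES = ("Tis", "T1", "T2", "T3", "T4", "NA")
N_STAGES = ("N0", "N1", "N2", "NA")
SEXES = ("male", "female")
TUMOR_SITES = ("colon", "rectum", "NA")
DIFFERENTIATIONS = ("low", "moderate", "high", "NA")
SPECIMENS = ("plasma", "leukocyte")

#: Maximal number of PCR cycles; Ct values live in (0, CT_CEILING].
CT_CEILING = 50.0

#: Minimum enrollment age (inclusion criterion).
MIN_AGE = 18

PLASMA_REPLICATES = 3

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "ajcc_stage",
    "t_stage",
    "n_stage",
    "sex",
    "age",
    "tumor_site",
    "tumor_size_cm",
    "differentiation",
    "specimen",
    "replicate_index",
    "ct_actb",
    "ct_msept9",
    "ct_msdc2",
]

ND_TOKEN = "ND"


class CohortFormatError(ValueError):
    """The file does not conform to the cohort CSV dialect."""


class CohortValidationError(ValueError):
    """The cohort violates a data-model invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations[:5])
        if len(violations) > 5:
            msg += f" (+{len(violations) - 5} more)"
        super().__init__(f"{len(violations)} cohort violation(s): {msg}")


@dataclass(frozen=True)
class Violation:
    """One broken invariant, attributable to a subject and field."""

    subject_id: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"[{self.subject_id}] {self.field}: {self.rule}"


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled individual."""

    subject_id: str
    group: str
    sex: str
    age: int
    ajcc_stage: str | None = None
    t_stage: str = "NA"
    n_stage: str = "NA"
    tumor_site: str = "NA"
    tumor_size_cm: float | None = None
    differentiation: str = "NA"


@dataclass(frozen=True)
class QpcrReaction:
    """One qPCR well; ``None`` Ct means no detectable amplification."""

    subject_id: str
    specimen: str
    replicate_index: int
    ct_actb: float | None
    ct_msept9: float | None
    ct_msdc2: float | None


@dataclass
class Cohort:
    """Subjects plus their reactions; see :func:`validate_cohort`."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    reactions: list[QpcrReaction] = field(default_factory=list)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def plasma_reactions(self, subject_id: str) -> list[QpcrReaction]:
        rs = [
            r
            for r in self.reactions
            if r.subject_id == subject_id and r.specimen == "plasma"
        ]
        return sorted(rs, key=lambda r: r.replicate_index)

    def leukocyte_reaction(self, subject_id: str) -> QpcrReaction | None:
        for r in self.reactions:
            if r.subject_id == subject_id and r.specimen == "leukocyte":
                return r
        return None

    def subjects_in_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)


def _check_enum(
    out: list[Violation], sid: str, fieldname: str, value: str, allowed: tuple
) -> None:
    if value not in allowed:
        out.append(
            Violation(sid, fieldname, f"value {value!r} not in {sorted(allowed)}")
        )


def _check_ct(out: list[Violation], sid: str, fieldname: str, ct: float | None) -> None:
    if ct is None:
        return
    if not (isinstance(ct, (int, float)) and math.isfinite(ct)):
        out.append(Violation(sid, fieldname, f"Ct {ct!r} is not a finite number"))
    elif not (0.0 < ct <= CT_CEILING):
        out.append(
            Violation(sid, fieldname, f"Ct {ct} outside (0, {CT_CEILING:g}]")
        )


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Return all invariant violations; the empty list means the cohort is valid.

    Violations are data, not exceptions: each names the subject, the field and
    the broken rule, so a caller can report every problem at once.
    """
    out: list[Violation] = []
    seen_ids: set[str] = set()
    for s in cohort.subjects:
        sid = s.subject_id
        if sid in seen_ids:
            out.append(Violation(sid, "subject_id", "duplicate subject_id"))
        seen_ids.add(sid)
        _check_enum(out, sid, "group", s.group, GROUPS)
        _check_enum(out, sid, "sex", s.sex, SEXES)
        _check_enum(out, sid, "t_stage", s.t_stage, T_STAGES)
        _check_enum(out, sid, "n_stage", s.n_stage, N_STAGES)
        _check_enum(out, sid, "tumor_site", s.tumor_site, TUMOR_SITES)
        _check_enum(out, sid, "differentiation", s.differentiation, DIFFERENTIATIONS)
        if s.group == "CRC":
            if s.ajcc_stage is None:
                out.append(
                    Violation(sid, "ajcc_stage", "CRC subjects require an AJCC stage")
                )
            else:
                _check_enum(out, sid, "ajcc_stage", s.ajcc_stage, AJCC_STAGES)
        elif s.ajcc_stage is not None:
            out.append(
                Violation(sid, "ajcc_stage", "AJCC stage only applies to CRC subjects")
            )
        if not (isinstance(s.age, int) and s.age >= MIN_AGE):
            out.append(
                Violation(
                    sid, "age", f"age {s.age!r} below inclusion minimum of {MIN_AGE}"
                )
            )
        if s.tumor_size_cm is not None and not (
            isinstance(s.tumor_size_cm, (int, float)) and s.tumor_size_cm >= 0
        ):
            out.append(
                Violation(sid, "tumor_size_cm", f"size {s.tumor_size_cm!r} negative")
            )

    by_subject: dict[str, dict[str, list[QpcrReaction]]] = {}
    for r in cohort.reactions:
        sid = r.subject_id
        if sid not in seen_ids:
            out.append(
                Violation(sid, "subject_id", "reaction references unknown subject")
            )
        _check_enum(out, sid, "specimen", r.specimen, SPECIMENS)
        _check_ct(out, sid, "ct_actb", r.ct_actb)
        _check_ct(out, sid, "ct_msept9", r.ct_msept9)
        _check_ct(out, sid, "ct_msdc2", r.ct_msdc2)
        by_subject.setdefault(sid, {}).setdefault(r.specimen, []).append(r)

    for sid, by_specimen in by_subject.items():
        plasma = by_specimen.get("plasma", [])
        if plasma:
            idx = sorted(r.replicate_index for r in plasma)
            if len(set(idx)) != len(idx):
                out.append(
                    Violation(
                        sid, "replicate_index", "duplicate plasma replicate_index"
                    )
                )
            if len(plasma) != PLASMA_REPLICATES or set(idx) - {1, 2, 3}:
                out.append(
                    Violation(
                        sid,
                        "specimen",
                        f"plasma requires exactly {PLASMA_REPLICATES} replicates "
                        f"with indices 1..3, found {idx}",
                    )
                )
        leuko = by_specimen.get("leukocyte", [])
        if leuko and (
            len(leuko) != 1 or leuko[0].replicate_index != 1
        ):
            out.append(
                Violation(
                    sid,
                    "specimen",
                    "leukocyte requires exactly 1 reaction with replicate_index 1",
                )
            )
    return out


def _parse_ct(raw: str, column: str, row_num: int) -> float | None:
    raw = raw.strip()
    if raw == "" or raw == ND_TOKEN:
        return None
    try:
        ct = float(raw)
    except ValueError:
        raise CohortFormatError(
            f"row {row_num}: {column} value {raw!r} is neither a Ct nor {ND_TOKEN!r}"
        ) from None
    if ct > CT_CEILING:
        raise CohortFormatError(
            f"row {row_num}: {column} Ct {ct} exceeds the {CT_CEILING:g}-cycle ceiling"
        )
    return ct


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV.

    Raises
    ------
    CohortFormatError
        Missing column, unparseable cell, or out-of-range Ct, with row number.
    CohortValidationError
        Any data-model invariant violation, with subject and rule.
    """
    path = Path(path)
    subjects: dict[str, SubjectRecord] = {}
    reactions: list[QpcrReaction] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file, expected a header")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for row_num, row in enumerate(reader, start=2):
            sid = row["subject_id"].strip()
            stage_raw = row["ajcc_stage"].strip()
            size_raw = row["tumor_size_cm"].strip()
            try:
                age = int(row["age"])
            except ValueError:
                raise CohortFormatError(
                    f"row {row_num}: age {row['age']!r} is not an integer"
                ) from None
            if size_raw in ("", "NA"):
                size = None
            else:
                try:
                    size = float(size_raw)
                except ValueError:
                    raise CohortFormatError(
                        f"row {row_num}: tumor_size_cm {size_raw!r} is not a number"
                    ) from None
            subject = SubjectRecord(
                subject_id=sid,
                group=row["group"].strip(),
                ajcc_stage=stage_raw or None,
                t_stage=row["t_stage"].strip() or "NA",
                n_stage=row["n_stage"].strip() or "NA",
                sex=row["sex"].strip(),
                age=age,
                tumor_site=row["tumor_site"].strip() or "NA",
                tumor_size_cm=size,
                differentiation=row["differentiation"].strip() or "NA",
            )
            if sid in subjects:
                if subjects[sid] != subject:
                    raise CohortFormatError(
                        f"row {row_num}: subject {sid} metadata differs between rows"
                    )
            else:
                subjects[sid] = subject
            try:
                rep = int(row["replicate_index"])
            except ValueError:
                raise CohortFormatError(
                    f"row {row_num}: replicate_index "
                    f"{row['replicate_index']!r} is not an integer"
                ) from None
            reactions.append(
                QpcrReaction(
                    subject_id=sid,
                    specimen=row["specimen"].strip(),
                    replicate_index=rep,
                    ct_actb=_parse_ct(row["ct_actb"], "ct_actb", row_num),
                    ct_msept9=_parse_ct(row["ct_msept9"], "ct_msept9", row_num),
                    ct_msdc2=_parse_ct(row["ct_msdc2"], "ct_msdc2", row_num),
                )
            )
    cohort = Cohort(subjects=list(subjects.values()), reactions=reactions)
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError(violations)
    return cohort


def _fmt_ct(ct: float | None) -> str:
    return ND_TOKEN if ct is None else repr(float(ct))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV; ``read_cohort`` of the result reproduces the cohort.

    Floats are written with shortest round-trip repr so the write/read
    composition is the identity field-for-field.
    """
    path = Path(path)
    by_id = {s.subject_id: s for s in cohort.subjects}
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in cohort.reactions:
            s = by_id[r.subject_id]
            writer.writerow(
                [
                    s.subject_id,
                    s.group,
                    s.ajcc_stage or "",
                    s.t_stage,
                    s.n_stage,
                    s.sex,
                    s.age,
                    s.tumor_site,
                    "NA" if s.tumor_size_cm is None else repr(float(s.tumor_size_cm)),
                    s.differentiation,
                    r.specimen,
                    r.replicate_index,
                    _fmt_ct(r.ct_actb),
                    _fmt_ct(r.ct_msept9),
                    _fmt_ct(r.ct_msdc2),
                ]
            )
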