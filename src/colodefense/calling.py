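"""ColoDefense scoring: validity, replicate detection, k-of-n calls, levels.

The assay multiplexes two methylation targets (mSEPT9, mSDC2) with the ACTB
internal control in one qPCR reaction; plasma is run in triplicate. The
calling rules are:

* a plasma sample is *invalid* when its ACTB Ct is greater than 35.0
  (insufficient input DNA) — Ct exactly 35.0 is still valid;
* a replicate *detects* mSEPT9 when its Ct is strictly below 45.0, and
  mSDC2 strictly below 50.0;
* mSEPT9 is *positive* on the 1-of-3 rule and mSDC2 on the 2-of-3 rule;
* the combined test is positive when either marker is positive;
* plasma methylation level is the mean Ct over the three replicates with
  undetected reactions set to 50 (the cycle ceiling), so lower mean Ct
  means more methylated target;
* leukocyte methylation level is ΔCt = Ct(target) − Ct(ACTB) from the
  single leukocyte reaction, again substituting 50 for an undetected
  target.

The study never states how ACTB is aggregated across the three plasma
replicates; the default takes the mean of the amplified replicates, with
``max`` (worst replicate) and ``per_replicate`` (every replicate must
amplify below threshold) selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .cohort import CT_CEILING, Cohort, QpcrReaction

MARKERS = ("mSEPT9", "mSDC2")

ACTB_POLICIES = ("mean", "max", "per_replicate")


@dataclass(frozen=True)
class CallingThresholds:
    """All tunable constants of the calling algorithm (cycles and counts)."""

    actb_validity_ct: float = 35.0
    detection_ct_msept9: float = 45.0
    detection_ct_msdc2: float = 50.0
    min_positive_replicates_msept9: int = 1
    min_positive_replicates_msdc2: int = 2
    total_replicates: int = 3
    ct_ceiling: float = CT_CEILING
    actb_aggregation: str = "mean"

    def __post_init__(self) -> None:
        for name in ("detection_ct_msept9", "detection_ct_msdc2"):
            thr = getattr(self, name)
            if not 0 < thr <= self.ct_ceiling:
                raise ValueError(f"{name}={thr} outside (0, {self.ct_ceiling}]")
        for name in (
            "min_positive_replicates_msept9",
            "min_positive_replicates_msdc2",
        ):
            k = getattr(self, name)
            if not 1 <= k <= self.total_replicates:
                raise ValueError(
                    f"{name}={k} outside 1..{self.total_replicates}"
                )
        if self.actb_aggregation not in ACTB_POLICIES:
            raise ValueError(
                f"actb_aggregation must be one of {ACTB_POLICIES}"
            )

    def detection_ct(self, marker: str) -> float:
        if marker == "mSEPT9":
            return self.detection_ct_msept9
        if marker == "mSDC2":
            return self.detection_ct_msdc2
        raise ValueError(f"unknown marker {marker!r}")

    def min_positive_replicates(self, marker: str) -> int:
        if marker == "mSEPT9":
            return self.min_positive_replicates_msept9
        if marker == "mSDC2":
            return self.min_positive_replicates_msdc2
        raise ValueError(f"unknown marker {marker!r}")


DEFAULT_THRESHOLDS = CallingThresholds()


@dataclass(frozen=True)
class SampleCall:
    """Per-subject plasma calling outcome.

    Positivity and level fields are ``None`` on invalid samples (no internal
    control, hence no interpretable result).
    """

    subject_id: str
    valid: bool
    msept9_positive: bool | None = None
    msdc2_positive: bool | None = None
    combined_positive: bool | None = None
    msept9_mean_ct: float | None = None
    msdc2_mean_ct: float | None = None
    msept9_detected_replicates: int | None = None
    msdc2_detected_replicates: int | None = None

    def __post_init__(self) -> None:
        if self.valid:
            if self.combined_positive != (
                self.msept9_positive or self.msdc2_positive
            ):
                raise ValueError(
                    "combined_positive must be the OR of the marker calls"
                )
        elif self.combined_positive is not None:
            raise ValueError("invalid samples carry no positivity")


@dataclass(frozen=True)
class LeukocyteLevel:
    """Leukocyte relative methylation per marker: ΔCt = Ct(target) − Ct(ACTB).

    Lower ΔCt means more methylated target relative to total genomic input.
    ``informative`` is False when ACTB itself failed to amplify, in which
    case both ΔCt fields are ``None``.
    """

    subject_id: str
    delta_ct_msept9: float | None
    delta_ct_msdc2: float | None
    informative: bool = True


def _require_plasma_triplet(
    reactions: Sequence[QpcrReaction], thresholds: CallingThresholds
) -> None:
    if len(reactions) != thresholds.total_replicates:
        raise ValueError(
            f"expected {thresholds.total_replicates} plasma replicates, "
            f"got {len(reactions)}"
        )
    for r in reactions:
        if r.specimen != "plasma":
            raise ValueError(f"expected plasma reactions, got {r.specimen!r}")


def assess_validity(
    reactions: Sequence[QpcrReaction],
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Apply the ACTB internal-control rule to one subject's replicate set.

    Invalid iff the aggregated ACTB Ct is strictly greater than the validity
    threshold (default 35.0); a replicate set with no amplified ACTB at all
    is invalid.
    """
    _require_plasma_triplet(reactions, thresholds)
    amplified = [r.ct_actb for r in reactions if r.ct_actb is not None]
    if thresholds.actb_aggregation == "per_replicate":
        if len(amplified) != len(reactions):
            return False
        return all(ct <= thresholds.actb_validity_ct for ct in amplified)
    if not amplified:
        return False
    if thresholds.actb_aggregation == "mean":
        agg = sum(amplified) / len(amplified)
    else:  # max: the worst amplified replicate decides
        agg = max(amplified)
    return agg <= thresholds.actb_validity_ct


def replicate_detected(
    marker: str,
    ct: float | None,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff the replicate's Ct is strictly below the marker's threshold."""
    if ct is None:
        return False
    return ct < thresholds.detection_ct(marker)


def call_marker(
    marker: str,
    replicate_cts: Sequence[float | None],
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, int]:
    """Score one marker by its k-of-n rule; returns (positive, detected_count)."""
    if len(replicate_cts) != thresholds.total_replicates:
        raise ValueError(
            f"expected {thresholds.total_replicates} replicate Cts, "
            f"got {len(replicate_cts)}"
        )
    detected = sum(
        replicate_detected(marker, ct, thresholds) for ct in replicate_cts
    )
    return detected >= thresholds.min_positive_replicates(marker), detected


def plasma_level(
    replicate_cts: Sequence[float | None],
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Mean Ct across replicates with undetected reactions set to the ceiling."""
    if len(replicate_cts) != thresholds.total_replicates:
        raise ValueError(
            f"expected {thresholds.total_replicates} replicate Cts, "
            f"got {len(replicate_cts)}"
        )
    vals = [thresholds.ct_ceiling if ct is None else ct for ct in replicate_cts]
    return sum(vals) / len(vals)


def call_sample(
    reactions: Sequence[QpcrReaction],
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> SampleCall:
    """Full per-subject plasma call: validity, both markers, combined OR."""
    _require_plasma_triplet(reactions, thresholds)
    subject_id = reactions[0].subject_id
    if not assess_validity(reactions, thresholds):
        return SampleCall(subject_id=subject_id, valid=False)
    sept_cts = [r.ct_msept9 for r in reactions]
    sdc_cts = [r.ct_msdc2 for r in reactions]
    sept_pos, sept_n = call_marker("mSEPT9", sept_cts, thresholds)
    sdc_pos, sdc_n = call_marker("mSDC2", sdc_cts, thresholds)
    return SampleCall(
        subject_id=subject_id,
        valid=True,
        msept9_positive=sept_pos,
        msdc2_positive=sdc_pos,
        combined_positive=sept_pos or sdc_pos,
        msept9_mean_ct=plasma_level(sept_cts, thresholds),
        msdc2_mean_ct=plasma_level(sdc_cts, thresholds),
        msept9_detected_replicates=sept_n,
        msdc2_detected_replicates=sdc_n,
    )


def leukocyte_level(
    reaction: QpcrReaction,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> LeukocyteLevel:
    """ΔCt per marker from the single leukocyte reaction.

    An undetected target is set to the Ct ceiling before subtraction; an
    undetected ACTB makes the whole sample uninformative.
    """
    if reaction.specimen != "leukocyte":
        raise ValueError(f"expected a leukocyte reaction, got {reaction.specimen!r}")
    if reaction.ct_actb is None:
        return LeukocyteLevel(reaction.subject_id, None, None, informative=False)
    ceil = thresholds.ct_ceiling
    sept = reaction.ct_msept9 if reaction.ct_msept9 is not None else ceil
    sdc = reaction.ct_msdc2 if reaction.ct_msdc2 is not None else ceil
    return LeukocyteLevel(
        subject_id=reaction.subject_id,
        delta_ct_msept9=sept - reaction.ct_actb,
        delta_ct_msdc2=sdc - reaction.ct_actb,
    )


def call_cohort(
    cohort: Cohort,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[SampleCall], list[LeukocyteLevel]]:
    """Call every plasma sample and compute every leukocyte ΔCt in the cohort."""
    calls: list[SampleCall] = []
    levels: list[LeukocyteLevel] = []
    for subject in cohort.subjects:
        plasma = cohort.plasma_reactions(subject.subject_id)
        if plasma:
            calls.append(call_sample(plasma, thresholds))
        leuko = cohort.leukocyte_reaction(subject.subject_id)
        if leuko is not None:
            levels.append(leukocyte_level(leuko, thresholds))
    return calls, levels


CALLS_COLUMNS = [
    "subject_id",
    "valid",
    "msept9_detected_replicates",
    "msept9_positive",
    "msdc2_detected_replicates",
    "msdc2_positive",
    "combined_positive",
    "msept9_mean_ct",
    "msdc2_mean_ct",
]

LEVELS_COLUMNS = [
    "subject_id",
    "informative",
    "delta_ct_msept9",
    "delta_ct_msdc2",
]


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.3f}"
    return str(value)


def write_calls(calls: Iterable[SampleCall], path: str | Path) -> None:
    """Write per-sample calls as TSV (Ct to 3 decimals, booleans true/false)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    _fmt(getattr(c, col)) for col in CALLS_COLUMNS
                )
                + "\n"
            )


def write_leukocyte_levels(
    levels: Iterable[LeukocyteLevel], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(LEVELS_COLUMNS) + "\n")
        for lv in levels:
            fh.write(
                "\t".join(_fmt(getattr(lv, col)) for col in LEVELS_COLUMNS) + "\n"
            )


def _parse_cell(raw: str, kind: str):
    if raw == "NA":
        return None
    if kind == "bool":
        return raw == "true"
    if kind == "int":
        return int(raw)
    return float(raw)


def read_calls(path: str | Path) -> list[SampleCall]:
    """Read a calls TSV written by :func:`write_calls`."""
    kinds = {
        "valid": "bool",
        "msept9_detected_replicates": "int",
        "msept9_positive": "bool",
        "msdc2_detected_replicates": "int",
        "msdc2_positive": "bool",
        "combined_positive": "bool",
        "msept9_mean_ct": "float",
        "msdc2_mean_ct": "float",
    }
    calls = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALLS_COLUMNS:
            raise ValueError(f"unexpected calls header: {header}")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            kwargs = {"subject_id": cells["subject_id"]}
            for col, kind in kinds.items():
                kwargs[col] = _parse_cell(cells[col], kind)
            calls.append(SampleCall(**kwargs))
    return calls
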