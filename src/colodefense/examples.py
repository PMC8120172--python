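"""Constructed example cohorts with prescribed replicate-detection patterns.

These builders assemble small synthetic cohorts whose integer positivity
counts are fixed by construction, so the calling pipeline's reported
percentages are forced exactly — the standard worked examples for the
printed rates of the validation study (e.g. 36 of 38 controls negative for
mSEPT9 gives a 94.7% specificity). Ct values within a pattern are drawn at
random inside the valid range for the pattern; they never change the call.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, QpcrReaction, SubjectRecord

#: (mSEPT9 detected replicates, mSDC2 detected replicates) per subject
Pattern = tuple[int, int]


def pattern_reactions(
    subject_id: str, pattern: Pattern, rng: np.random.Generator
) -> list[QpcrReaction]:
    """Three plasma replicates realizing the given detection pattern.

    Detected mSEPT9 replicates draw Ct in (38, 44) — below the 45-cycle
    threshold — and detected mSDC2 replicates in (42, 49); ACTB always
    amplifies in (26, 31) so every sample is valid.
    """
    sept_n, sdc_n = pattern
    if not (0 <= sept_n <= 3 and 0 <= sdc_n <= 3):
        raise ValueError(f"pattern counts must be 0..3, got {pattern}")
    out = []
    for rep in range(3):
        sept = (
            round(float(rng.uniform(38, 44)), 2) if rep < sept_n else None
        )
        sdc = round(float(rng.uniform(42, 49)), 2) if rep < sdc_n else None
        out.append(
            QpcrReaction(
                subject_id=subject_id,
                specimen="plasma",
                replicate_index=rep + 1,
                ct_actb=round(float(rng.uniform(26, 31)), 2),
                ct_msept9=sept,
                ct_msdc2=sdc,
            )
        )
    return out


def build_fixture_cohort(
    group: str,
    patterns: list[Pattern],
    rng: np.random.Generator,
    stages: list[str] | None = None,
    id_prefix: str = "F",
) -> Cohort:
    """One plasma-only fixture cohort: one subject per detection pattern."""
    if stages is not None and len(stages) != len(patterns):
        raise ValueError("stages must match patterns in length")
    subjects, reactions = [], []
    for i, pattern in enumerate(patterns):
        sid = f"{id_prefix}{i + 1:03d}"
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                sex="male" if i % 2 == 0 else "female",
                age=int(rng.integers(30, 80)),
                ajcc_stage=stages[i] if stages is not None else None,
            )
        )
        reactions.extend(pattern_reactions(sid, pattern, rng))
    return Cohort(subjects=subjects, reactions=reactions)


def control_msept9_fixture(rng: np.random.Generator) -> Cohort:
    """38 controls; exactly 2 have one mSEPT9-detected replicate (1/3-rule
    positive), the rest carry no detectable methylation → mSEPT9
    specificity 36/38."""
    patterns: list[Pattern] = [(1, 0)] * 2 + [(0, 0)] * 36
    return build_fixture_cohort("Control", patterns, rng, id_prefix="C")


def control_combined_fixture(rng: np.random.Generator) -> Cohort:
    """38 controls; 5 satisfy at least one marker rule (2 via 1/3 mSEPT9
    with concordant mSDC2, 3 via 2/3 mSDC2 alone) → combined specificity
    33/38."""
    patterns: list[Pattern] = (
        [(1, 3)] * 2 + [(0, 2)] * 3 + [(0, 0)] * 33
    )
    return build_fixture_cohort("Control", patterns, rng, id_prefix="C")


def adenoma_fixture(rng: np.random.Generator) -> Cohort:
    """49 adenoma patients; 12 meet a positivity rule (7 mSEPT9, 5 mSDC2)
    → combined detection rate 12/49."""
    patterns: list[Pattern] = (
        [(1, 0)] * 7 + [(0, 2)] * 5 + [(0, 0)] * 37
    )
    return build_fixture_cohort("Ade", patterns, rng, id_prefix="A")


def early_stage_fixture(rng: np.random.Generator) -> Cohort:
    """44 stage 0-II CRC cases (4 stage 0, 9 stage I, 31 stage II); 36 are
    combined-positive of which 30 are mSEPT9-positive → sensitivities
    30/44 (mSEPT9) and 36/44 (combined)."""
    patterns: list[Pattern] = (
        [(2, 1)] * 15  # mSEPT9-positive, sub-threshold mSDC2 signal
        + [(1, 0)] * 15  # mSEPT9-positive only
        + [(0, 2)] * 6  # mSDC2-positive only
        + [(0, 1)] * 4  # single mSDC2 replicate: below the 2/3 rule
        + [(0, 0)] * 4
    )
    stages = ["0"] * 4 + ["I"] * 9 + ["II"] * 31
    return build_fixture_cohort("CRC", patterns, rng, stages=stages, id_prefix="E")


def crc_full_fixture(rng: np.random.Generator) -> Cohort:
    """91 CRC cases with the study's stage mix and marker counts forced to
    69 mSEPT9-positive, 55 mSDC2-positive, 78 either-positive (overlap 46)
    → sensitivities 75.8 / 60.4 / 85.7%."""
    patterns: list[Pattern] = (
        [(1, 2)] * 46  # positive for both markers
        + [(1, 1)] * 23  # mSEPT9 only
        + [(0, 2)] * 9  # mSDC2 only
        + [(0, 0)] * 13
    )
    stages = (
        ["0"] * 4 + ["I"] * 9 + ["II"] * 31 + ["III"] * 29 + ["IV"] * 4
        + ["unknown"] * 14
    )
    order = rng.permutation(len(patterns))
    patterns = [patterns[i] for i in order]
    return build_fixture_cohort("CRC", patterns, rng, stages=stages, id_prefix="K")
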