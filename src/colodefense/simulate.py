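"""Seeded synthetic cohorts with the study's case-control structure.

The generator emulates a 213-subject colorectal-cancer case-control cohort:
91 CRC cases (stage mix 4/9/31/29/4 for stages 0-IV plus 14 of unknown
stage), 49 adenoma, 27 hyperplastic-polyp, 8 other-gastrointestinal-tumor
patients and 38 colonoscopy-normal controls. Each subject contributes three
plasma qPCR replicates and one leukocyte reaction.

Plasma methylation signal is modeled at the replicate level: each replicate
detects a marker with a group-specific probability, and detected replicates
draw a Ct from a truncated normal below the marker's detection threshold.
The default detection probabilities are calibrated (by inverting the k-of-n
binomial rule) so the expected sample-level positivity matches the study's
printed rates — e.g. 75.8% mSEPT9 / 60.4% mSDC2 in CRC and 5.3% / 13.2% in
controls. CRC detected-Ct means shift downward with stage so later-stage
plasma carries more methylated DNA. Leukocyte ΔCt is drawn from the same
normal distribution in every group: the generator's null hypothesis is that
leukocyte methylation carries no disease signal.

All randomness flows from one seed through three spawned child streams
(demographics, plasma, leukocyte), so the same seed yields byte-identical
cohort CSVs regardless of which other module functions ran before.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .calling import CallingThresholds, DEFAULT_THRESHOLDS, call_cohort
from .cohort import (
    AJCC_STAGES,
    CT_CEILING,
    Cohort,
    GROUPS,
    QpcrReaction,
    SubjectRecord,
)

PLASMA_RULES = {"mSEPT9": (1, 3), "mSDC2": (2, 3)}


def sensitivity_from_replicate_prob(p: float, rule: tuple[int, int]) -> float:
    """Expected sample-level positivity P(Binomial(n, p) >= k) under
    independent replicates, for the k-of-n scoring rule."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability {p} outside [0, 1]")
    k, n = rule
    return float(stats.binom.sf(k - 1, n, p))


def calibrate_to_target(
    sample_sensitivity: float, rule: tuple[int, int]
) -> float:
    """Invert :func:`sensitivity_from_replicate_prob` by monotone bisection.

    Returns the per-replicate detection probability whose expected
    sample-level positivity equals the target to within 1e-9.
    """
    if not 0 <= sample_sensitivity <= 1:
        raise ValueError(
            f"target sensitivity {sample_sensitivity} outside [0, 1]"
        )
    if sample_sensitivity in (0.0, 1.0):
        return sample_sensitivity
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if sensitivity_from_replicate_prob(mid, rule) < sample_sensitivity:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    return (lo + hi) / 2


@dataclass(frozen=True)
class PlasmaMarkerParams:
    """Replicate-level detection probability and detected-Ct distribution."""

    detection_prob: float
    ct_mean: float
    ct_sd: float
    ct_lower: float = 20.0

    def __post_init__(self) -> None:
        if not 0 <= self.detection_prob <= 1:
            raise ValueError(f"detection_prob {self.detection_prob} outside [0,1]")
        if self.ct_sd <= 0:
            raise ValueError("ct_sd must be positive")


@dataclass(frozen=True)
class Demographics:
    age_mean: float
    age_sd: float
    age_min: int
    age_max: int
    male_fraction: float


#: Sample-level positivity rates the defaults are calibrated to.
TARGET_SAMPLE_RATES: dict[str, dict[str, float]] = {
    "CRC": {"mSEPT9": 0.758, "mSDC2": 0.604},
    "Ade": {"mSEPT9": 0.143, "mSDC2": 0.122},
    "HP": {"mSEPT9": 0.111, "mSDC2": 0.125},
    "OtherTumor": {"mSEPT9": 0.125, "mSDC2": 0.143},
    "Control": {"mSEPT9": 0.053, "mSDC2": 0.132},
}

_DETECTED_CT_MEANS = {
    "CRC": {"mSEPT9": (38.0, 3.0), "mSDC2": (40.0, 3.0)},
    "other": {"mSEPT9": (42.0, 2.0), "mSDC2": (45.0, 2.5)},
}


def default_plasma_params() -> dict[str, dict[str, PlasmaMarkerParams]]:
    out: dict[str, dict[str, PlasmaMarkerParams]] = {}
    for group in GROUPS:
        means = _DETECTED_CT_MEANS["CRC" if group == "CRC" else "other"]
        out[group] = {}
        for marker, rule in PLASMA_RULES.items():
            p = calibrate_to_target(TARGET_SAMPLE_RATES[group][marker], rule)
            mean, sd = means[marker]
            out[group][marker] = PlasmaMarkerParams(
                detection_prob=p, ct_mean=mean, ct_sd=sd
            )
    return out


def default_demographics() -> dict[str, Demographics]:
    return {
        "Ade": Demographics(54.6, 11.7, 29, 78, 0.796),
        "HP": Demographics(52.5, 11.2, 27, 77, 0.593),
        "OtherTumor": Demographics(49.6, 9.6, 38, 68, 0.5),
        "Control": Demographics(47.2, 14.5, 20, 81, 0.526),
        "CRC:0": Demographics(70.3, 10.4, 53, 80, 0.0),
        "CRC:I": Demographics(56.3, 12.3, 30, 72, 0.333),
        "CRC:II": Demographics(60.9, 12.8, 36, 85, 0.742),
        "CRC:III": Demographics(64.5, 12.7, 25, 89, 0.621),
        "CRC:IV": Demographics(62.5, 10.2, 55, 80, 0.75),
        "CRC:unknown": Demographics(64.7, 18.4, 22, 86, 0.643),
    }


def default_crc_descriptors() -> dict[str, dict[str, int]]:
    """Marginal counts of the CRC tumor descriptors (per 91 cases)."""
    return {
        "t_stage": {"Tis": 4, "T1": 1, "T2": 13, "T3": 49, "T4": 9, "NA": 15},
        "n_stage": {"N0": 45, "N1": 23, "N2": 8, "NA": 15},
        "tumor_site": {"colon": 29, "rectum": 59, "NA": 3},
        "tumor_size": {"<=4": 34, ">4": 36, "NA": 21},
        "differentiation": {"low": 5, "moderate": 41, "high": 20, "NA": 25},
    }


@dataclass
class SimulationConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "CRC": 91,
            "Ade": 49,
            "HP": 27,
            "OtherTumor": 8,
            "Control": 38,
        }
    )
    crc_stage_mix: dict[str, int] = field(
        default_factory=lambda: {
            "0": 4,
            "I": 9,
            "II": 31,
            "III": 29,
            "IV": 4,
            "unknown": 14,
        }
    )
    plasma: dict[str, dict[str, PlasmaMarkerParams]] = field(
        default_factory=default_plasma_params
    )
    #: Added to the CRC detected-Ct mean; later stage → lower Ct.
    crc_stage_ct_shift: dict[str, float] = field(
        default_factory=lambda: {
            "0": 3.0,
            "I": 2.0,
            "II": 0.0,
            "III": -1.0,
            "IV": -2.5,
            "unknown": 0.0,
        }
    )
    actb_ct_mean: float = 28.0
    actb_ct_sd: float = 1.5
    actb_ct_bounds: tuple[float, float] = (20.0, 35.0)
    leukocyte_actb_mean: float = 22.0
    leukocyte_actb_sd: float = 1.0
    #: per-marker (mean, sd) of leukocyte ΔCt, identical across groups
    leukocyte_delta_ct: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"mSEPT9": (12.0, 1.5), "mSDC2": (5.0, 1.5)}
    )
    invalid_sample_prob: float = 0.0
    #: optional per-group fraction of "shedders"; non-shedders never detect
    shedding_fraction: dict[str, float] | None = None
    demographics: dict[str, Demographics] = field(
        default_factory=default_demographics
    )
    crc_descriptors: dict[str, dict[str, int]] = field(
        default_factory=default_crc_descriptors
    )
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"group size for {g} negative")
        if sum(self.crc_stage_mix.values()) != self.group_sizes.get("CRC", 0):
            raise ValueError("crc_stage_mix must sum to the CRC group size")
        for s in self.crc_stage_mix:
            if s not in AJCC_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not 0 <= self.invalid_sample_prob <= 1:
            raise ValueError("invalid_sample_prob outside [0, 1]")
        if self.shedding_fraction is not None:
            for g, f in self.shedding_fraction.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"shedding fraction for {g} outside [0, 1]")
        for g in (g for g, n in self.group_sizes.items() if n > 0):
            if g not in self.plasma:
                raise ValueError(f"no plasma parameters for group {g}")


@dataclass
class GeneratorReport:
    seed: int
    group_counts: dict[str, int]
    stage_counts: dict[str, int]
    empirical_positivity: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "group_counts": self.group_counts,
            "stage_counts": self.stage_counts,
            "empirical_positivity": self.empirical_positivity,
        }


def _trunc_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _scaled_counts(counts: Mapping[str, int], n: int) -> dict[str, int]:
    """Rescale marginal counts to total n by largest remainder."""
    total = sum(counts.values())
    if total == 0 or n == 0:
        return {k: 0 for k in counts}
    raw = {k: v * n / total for k, v in counts.items()}
    out = {k: math.floor(v) for k, v in raw.items()}
    short = n - sum(out.values())
    for k in sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)[:short]:
        out[k] += 1
    return out


def _descriptor_assignment(
    rng: np.random.Generator, counts: Mapping[str, int], n: int
) -> list[str]:
    scaled = _scaled_counts(counts, n)
    values = [k for k, c in scaled.items() for _ in range(c)]
    return [values[i] for i in rng.permutation(n)]


def simulate_cohort(
    config: SimulationConfig | None = None,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[Cohort, GeneratorReport]:
    """Draw one cohort from the generative model; identical config+seed give
    byte-identical cohorts.

    ``thresholds`` supplies the per-marker detection ceilings the detected-Ct
    distributions are truncated to, and the scoring rules the report's
    empirical positivity is computed with.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    demo_rng, plasma_rng, leuko_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    subjects: list[SubjectRecord] = []
    reactions: list[QpcrReaction] = []

    # CRC tumor descriptors: marginal composition scaled to the group size,
    # assigned independently across stratifiers.
    n_crc = config.group_sizes.get("CRC", 0)
    desc = {
        name: _descriptor_assignment(demo_rng, counts, n_crc)
        for name, counts in config.crc_descriptors.items()
    }
    size_values: list[float | None] = []
    for cat in desc.get("tumor_size", []):
        if cat == "NA":
            size_values.append(None)
        elif cat == "<=4":
            size_values.append(round(float(demo_rng.uniform(1.0, 4.0)), 1))
        else:
            size_values.append(round(float(demo_rng.uniform(4.1, 9.0)), 1))

    # (group, stage, segment size) in fixed order: determinism by construction
    segments: list[tuple[str, str | None, int]] = []
    for stage in ("0", "I", "II", "III", "IV", "unknown"):
        k = config.crc_stage_mix.get(stage, 0)
        if k:
            segments.append(("CRC", stage, k))
    for group in ("Ade", "HP", "OtherTumor", "Control"):
        k = config.group_sizes.get(group, 0)
        if k:
            segments.append((group, None, k))

    counter = 0
    crc_index = 0
    markers = ("mSEPT9", "mSDC2")
    for group, stage, n_seg in segments:
        demo_key = f"CRC:{stage}" if group == "CRC" else group
        demo = config.demographics[demo_key]
        lo = max(demo.age_min, 18)
        ages = np.rint(
            _trunc_normal(
                demo_rng, demo.age_mean, demo.age_sd, lo - 0.49, demo.age_max + 0.49,
                n_seg,
            )
        ).astype(int)
        ages = np.clip(ages, lo, demo.age_max)
        male = demo_rng.random(n_seg) < demo.male_fraction

        # plasma replicate-level draws, vectorized over the segment
        invalid = plasma_rng.random(n_seg) < config.invalid_sample_prob
        actb = _trunc_normal(
            plasma_rng,
            config.actb_ct_mean,
            config.actb_ct_sd,
            *config.actb_ct_bounds,
            size=n_seg * 3,
        ).reshape(n_seg, 3)
        marker_cts: dict[str, np.ndarray] = {}
        marker_detected: dict[str, np.ndarray] = {}
        for marker in markers:
            params = config.plasma[group][marker]
            detected = plasma_rng.random((n_seg, 3)) < params.detection_prob
            if config.shedding_fraction is not None:
                frac = config.shedding_fraction.get(group, 1.0)
                sheds = plasma_rng.random(n_seg) < frac
                detected &= sheds[:, None]
            shift = (
                config.crc_stage_ct_shift.get(stage, 0.0)
                if group == "CRC"
                else 0.0
            )
            upper = thresholds.detection_ct(marker)
            mean = min(params.ct_mean + shift, upper - 1e-6)
            cts = _trunc_normal(
                plasma_rng, mean, params.ct_sd, params.ct_lower, upper,
                n_seg * 3,
            ).reshape(n_seg, 3)
            marker_cts[marker] = cts
            marker_detected[marker] = detected

        leuko_actb = _trunc_normal(
            leuko_rng,
            config.leukocyte_actb_mean,
            config.leukocyte_actb_sd,
            *config.actb_ct_bounds,
            size=n_seg,
        )
        leuko_delta = {
            marker: leuko_rng.normal(*config.leukocyte_delta_ct[marker], n_seg)
            for marker in markers
        }

        for i in range(n_seg):
            counter += 1
            sid = f"S{counter:04d}"
            kwargs: dict = {}
            if group == "CRC":
                kwargs = {
                    "ajcc_stage": stage,
                    "t_stage": desc["t_stage"][crc_index],
                    "n_stage": desc["n_stage"][crc_index],
                    "tumor_site": desc["tumor_site"][crc_index],
                    "tumor_size_cm": size_values[crc_index],
                    "differentiation": desc["differentiation"][crc_index],
                }
                crc_index += 1
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    sex="male" if male[i] else "female",
                    age=int(ages[i]),
                    **kwargs,
                )
            )
            for rep in range(3):
                cts: dict[str, float | None] = {}
                for marker in markers:
                    if marker_detected[marker][i, rep]:
                        cts[marker] = round(float(marker_cts[marker][i, rep]), 2)
                    else:
                        cts[marker] = None
                reactions.append(
                    QpcrReaction(
                        subject_id=sid,
                        specimen="plasma",
                        replicate_index=rep + 1,
                        ct_actb=None if invalid[i] else round(float(actb[i, rep]), 2),
                        ct_msept9=cts["mSEPT9"],
                        ct_msdc2=cts["mSDC2"],
                    )
                )
            leuko_cts: dict[str, float | None] = {}
            for marker in markers:
                ct = float(leuko_actb[i] + leuko_delta[marker][i])
                leuko_cts[marker] = round(ct, 2) if ct < CT_CEILING else None
            reactions.append(
                QpcrReaction(
                    subject_id=sid,
                    specimen="leukocyte",
                    replicate_index=1,
                    ct_actb=round(float(leuko_actb[i]), 2),
                    ct_msept9=leuko_cts["mSEPT9"],
                    ct_msdc2=leuko_cts["mSDC2"],
                )
            )

    cohort = Cohort(subjects=subjects, reactions=reactions)
    report = _generator_report(cohort, config, thresholds)
    return cohort, report


def _generator_report(
    cohort: Cohort, config: SimulationConfig, thresholds: CallingThresholds
) -> GeneratorReport:
    group_counts = {g: len(cohort.subjects_in_group(g)) for g in GROUPS}
    stage_counts: dict[str, int] = {}
    for s in cohort.subjects_in_group("CRC"):
        stage_counts[s.ajcc_stage] = stage_counts.get(s.ajcc_stage, 0) + 1
    calls, _ = call_cohort(cohort, thresholds)
    group_of = {s.subject_id: s.group for s in cohort.subjects}
    positivity: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        valid = [
            c for c in calls if group_of[c.subject_id] == g and c.valid
        ]
        if not valid:
            continue
        positivity[g] = {
            "mSEPT9": sum(c.msept9_positive for c in valid) / len(valid),
            "mSDC2": sum(c.msdc2_positive for c in valid) / len(valid),
            "combined": sum(c.combined_positive for c in valid) / len(valid),
        }
    return GeneratorReport(
        seed=config.seed,
        group_counts=group_counts,
        stage_counts=stage_counts,
        empirical_positivity=positivity,
    )
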