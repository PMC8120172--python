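"""Diagnostic performance, ROC/AUC, stratified tables and group comparisons.

Sensitivity is the positive-call rate among cases and specificity the
negative-call rate among controls, each with a Wilson score 95% interval
(Clopper-Pearson selectable). ROC curves are built from plasma mean Ct,
with lower Ct meaning more methylation and hence more disease-like; the
AUC confidence interval uses DeLong's large-sample variance, with a seeded
bootstrap alternative. Group-level comparisons follow the study's toolkit:
Mann-Whitney U for methylation levels, Pearson chi-square for rates across
more than two groups, and the two-sample t-test for two-group means.

Reported percentages are rounded to one decimal, half away from zero, only
at the reporting layer; everything internal is full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .calling import SampleCall
from .cohort import (
    AJCC_STAGES,
    Cohort,
    DIFFERENTIATIONS,
    N_STAGES,
    T_STAGES,
    TUMOR_SITES,
)

CI_METHODS = ("wilson", "clopper_pearson")
COMBINED_SCORE_METHODS = ("min", "mean")


class DegenerateTableError(ValueError):
    """A contingency table with a zero margin admits no chi-square test."""


class InconsistentStratumError(ValueError):
    """A printed stratum percentage is incompatible with any integer count."""


def round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass(frozen=True)
class DiagnosticPerformance:
    n_cases: int
    n_controls: int
    true_positives: int
    true_negatives: int
    sensitivity_pct: float
    specificity_pct: float
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "true_positives": self.true_positives,
            "true_negatives": self.true_negatives,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "sensitivity_ci95": list(self.sensitivity_ci95),
            "specificity_ci95": list(self.specificity_ci95),
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


@dataclass(frozen=True)
class RocResult:
    points: list[tuple[float, float]]
    auc: float
    auc_ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci95": list(self.auc_ci95),
            "n_points": len(self.points),
        }


def _proportion_ci_pct(k: int, n: int, method: str) -> tuple[float, float]:
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return (round1(100 * lo), round1(100 * hi))


def diagnostic_performance(
    case_calls: Sequence[bool],
    control_calls: Sequence[bool],
    ci_method: str = "wilson",
) -> DiagnosticPerformance:
    """Sensitivity/specificity with 95% CIs from boolean positivity calls."""
    if not case_calls or not control_calls:
        raise ValueError("case and control call lists must be nonempty")
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {CI_METHODS}")
    n_cases, n_controls = len(case_calls), len(control_calls)
    tp = sum(bool(c) for c in case_calls)
    tn = sum(not c for c in control_calls)
    return DiagnosticPerformance(
        n_cases=n_cases,
        n_controls=n_controls,
        true_positives=tp,
        true_negatives=tn,
        sensitivity_pct=round1(100 * tp / n_cases),
        specificity_pct=round1(100 * tn / n_controls),
        sensitivity_ci95=_proportion_ci_pct(tp, n_cases, ci_method),
        specificity_ci95=_proportion_ci_pct(tn, n_controls, ci_method),
    )


def pool_strata(
    strata: Sequence[tuple[int, float]], tolerance: float = 1e-9
) -> float:
    """Reconstruct a pooled percentage from per-stratum (n, percent) rows.

    Each stratum's positive count is recovered as the nearest integer to
    n·percent/100. The consistency bound is deliberately lenient — half a
    count plus tolerance — because published one-decimal percentages can be
    off by a unit in the last digit; only a percentage that admits no
    nearby integer count at all (non-finite or outside [0, 100]) is
    rejected.
    """
    total_n = 0
    total_pos = 0
    for n, pct in strata:
        if n <= 0:
            raise ValueError(f"stratum size must be positive, got {n}")
        if not math.isfinite(pct) or not 0 <= pct <= 100:
            raise InconsistentStratumError(
                f"{pct!r}% is not a valid stratum percentage"
            )
        k = math.floor(n * pct / 100 + 0.5)
        if abs(n * pct / 100 - k) > 0.5 + tolerance:
            raise InconsistentStratumError(
                f"no integer count of {n} reproduces {pct}%"
            )
        total_n += n
        total_pos += k
    return round1(100 * total_pos / total_n)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_auc_variance(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[float, float]:
    """Tie-corrected AUC (higher score = more disease-like) and its
    DeLong sampling variance via the structural-component decomposition."""
    m, n = len(case_scores), len(control_scores)
    all_scores = np.concatenate([case_scores, control_scores])
    tz = _midrank(all_scores)
    tx = _midrank(case_scores)
    ty = _midrank(control_scores)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n  # per-case components
    v10 = 1.0 - (tz[m:] - ty) / m  # per-control components
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_curve(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    lower_is_disease: bool = True,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    rng: np.random.Generator | None = None,
) -> RocResult:
    """Empirical ROC and tie-corrected AUC for a case/control score contrast.

    ``lower_is_disease`` declares the score orientation (True for Ct, where
    less cycles mean more target DNA). The AUC equals the probability that a
    random case scores more disease-like than a random control, counting
    ties as one half.
    """
    if not len(case_scores) or not len(control_scores):
        raise ValueError("score lists must be nonempty")
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if lower_is_disease:
        cases, controls = -cases, -controls
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    s = np.concatenate([cases, controls])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    auc, var = _delong_auc_variance(cases, controls)
    if var == 0.0 and np.ptp(s) == 0.0:
        warnings.warn(
            "constant scores in both groups: AUC 0.5 with degenerate CI",
            stacklevel=2,
        )
        return RocResult(points=points, auc=0.5, auc_ci95=(0.5, 0.5))
    if ci_method == "delong":
        half = 1.959963984540054 * math.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0) if rng is None else rng
        aucs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            cb = rng.choice(cases, size=len(cases), replace=True)
            kb = rng.choice(controls, size=len(controls), replace=True)
            aucs[b], _ = _delong_auc_variance(cb, kb)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return RocResult(points=points, auc=auc, auc_ci95=ci)


def combined_score(
    msept9_mean_ct: float, msdc2_mean_ct: float, method: str = "min"
) -> float:
    """One scalar from the two mean Cts for the combined-test ROC.

    The default takes the minimum — the strongest methylation evidence —
    mirroring the OR structure of the calling rule; ``mean`` averages the
    two markers instead.
    """
    if method == "min":
        return min(msept9_mean_ct, msdc2_mean_ct)
    if method == "mean":
        return (msept9_mean_ct + msdc2_mean_ct) / 2
    raise ValueError(f"method must be one of {COMBINED_SCORE_METHODS}")


#: Largest n_a * n_b for which the exact Mann-Whitney null is enumerated.
EXACT_MW_LIMIT = 400


def mann_whitney(
    levels_a: Sequence[float], levels_b: Sequence[float]
) -> TestResult:
    """Two-sided Mann-Whitney U test on two sets of methylation levels.

    Exact enumeration when n_a·n_b ≤ 400 and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) * len(b) <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney",
    )


def pearson_chi_square(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r×c contingency table of counts."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table entries must be nonnegative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(chi2), p_value=float(p), method="pearson_chi_square"
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test; pooled variance by default, Welch optional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="t_test")
        return TestResult(
            statistic=math.copysign(math.inf, a.mean() - b.mean()),
            p_value=0.0,
            method="t_test",
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method="t_test"
    )


# ---------------------------------------------------------------------------
# Stratified sensitivity table

AGE_BINS = ("<40", "40-49", "50-59", "60-69", "70-79", ">=80")
SIZE_BINS = ("<=4 cm", ">4 cm", "NA")


def age_bin(age: int) -> str:
    if age < 40:
        return "<40"
    if age >= 80:
        return ">=80"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def size_bin(size_cm: float | None) -> str:
    if size_cm is None:
        return "NA"
    return "<=4 cm" if size_cm <= 4 else ">4 cm"


@dataclass(frozen=True)
class StratumRow:
    stratifier: str
    stratum: str
    n: int
    msept9_positives: int
    msdc2_positives: int
    combined_positives: int

    def sensitivity_pct(self, marker: str) -> float | None:
        if self.n == 0:
            return None
        k = {
            "mSEPT9": self.msept9_positives,
            "mSDC2": self.msdc2_positives,
            "combined": self.combined_positives,
        }[marker]
        return round1(100 * k / self.n)


@dataclass
class StratifiedReport:
    """Sensitivities of each marker and the combined test per case stratum.

    ``tests`` maps stratifier → marker → chi-square heterogeneity result
    (``None`` when fewer than two informative strata remain).
    """

    rows: list[StratumRow] = field(default_factory=list)
    tests: dict[str, dict[str, TestResult | None]] = field(default_factory=dict)
    include_na_in_test: bool = False

    def rows_for(self, stratifier: str) -> list[StratumRow]:
        return [r for r in self.rows if r.stratifier == stratifier]

    def to_tsv(self) -> str:
        lines = [
            "stratifier\tstratum\tn\tmsept9_sensitivity_pct\tmsept9_p\t"
            "msdc2_sensitivity_pct\tmsdc2_p\tcombined_sensitivity_pct\tcombined_p"
        ]
        seen: set[str] = set()
        for r in self.rows:
            cells = [r.stratifier, r.stratum, str(r.n)]
            for marker in ("mSEPT9", "mSDC2", "combined"):
                s = r.sensitivity_pct(marker)
                cells.append("NA" if s is None else f"{s:.1f}")
                if r.stratifier not in seen:
                    t = self.tests.get(r.stratifier, {}).get(marker)
                    cells.append("NA" if t is None else f"{t.p_value:.3f}")
                else:
                    cells.append("")
            seen.add(r.stratifier)
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


_STRATIFIERS: dict[str, tuple[tuple[str, ...], object]] = {
    "gender": (("male", "female"), lambda s: s.sex),
    "age_group": (AGE_BINS, lambda s: age_bin(s.age)),
    "t_stage": (T_STAGES, lambda s: s.t_stage),
    "n_stage": (N_STAGES, lambda s: s.n_stage),
    "tumor_site": (TUMOR_SITES, lambda s: s.tumor_site),
    "tumor_size": (SIZE_BINS, lambda s: size_bin(s.tumor_size_cm)),
    "differentiation": (DIFFERENTIATIONS, lambda s: s.differentiation),
}

_NA_STRATA = {"NA"}


def _hetero_test(rows: list[StratumRow], marker: str) -> TestResult | None:
    attr = {
        "mSEPT9": "msept9_positives",
        "mSDC2": "msdc2_positives",
        "combined": "combined_positives",
    }[marker]
    table = [
        [getattr(r, attr), r.n - getattr(r, attr)] for r in rows if r.n > 0
    ]
    if len(table) < 2:
        return None
    arr = np.asarray(table)
    # all-positive or all-negative strata: observed equals expected exactly
    if (arr.sum(axis=0) == 0).any():
        return TestResult(statistic=0.0, p_value=1.0, method="pearson_chi_square")
    return pearson_chi_square(table)


def stratified_report(
    cohort: Cohort,
    calls: Sequence[SampleCall],
    group: str = "CRC",
    include_na_in_test: bool = False,
) -> StratifiedReport:
    """Per-stratum sensitivities for valid cases, with heterogeneity tests.

    Strata follow the study's layout: gender, decade age bins (<40 … ≥80),
    T/N stage, tumor site, size ≤4 vs >4 cm, and differentiation, each with
    an explicit N/A stratum. By default the N/A row is displayed but left
    out of the chi-square test.
    """
    by_id = {c.subject_id: c for c in calls}
    cases = [
        s
        for s in cohort.subjects_in_group(group)
        if s.subject_id in by_id and by_id[s.subject_id].valid
    ]
    report = StratifiedReport(include_na_in_test=include_na_in_test)
    for name, (strata, keyfn) in _STRATIFIERS.items():
        rows = []
        for stratum in strata:
            members = [s for s in cases if keyfn(s) == stratum]
            counts = {"mSEPT9": 0, "mSDC2": 0, "combined": 0}
            for s in members:
                c = by_id[s.subject_id]
                counts["mSEPT9"] += bool(c.msept9_positive)
                counts["mSDC2"] += bool(c.msdc2_positive)
                counts["combined"] += bool(c.combined_positive)
            rows.append(
                StratumRow(
                    stratifier=name,
                    stratum=stratum,
                    n=len(members),
                    msept9_positives=counts["mSEPT9"],
                    msdc2_positives=counts["mSDC2"],
                    combined_positives=counts["combined"],
                )
            )
        assert sum(r.n for r in rows) == len(cases)
        report.rows.extend(rows)
        testable = [
            r
            for r in rows
            if include_na_in_test or r.stratum not in _NA_STRATA
        ]
        report.tests[name] = {
            marker: _hetero_test(testable, marker)
            for marker in ("mSEPT9", "mSDC2", "combined")
        }
    return report


# ---------------------------------------------------------------------------
# Whole-cohort evaluation

STAGE_SUBSETS = {"stage_0_II": ("0", "I", "II"), "stage_III_IV": ("III", "IV")}


def _calls_for(
    cohort: Cohort,
    calls_by_id: dict[str, SampleCall],
    group: str,
    stages: tuple[str, ...] | None = None,
) -> list[SampleCall]:
    out = []
    for s in cohort.subjects_in_group(group):
        c = calls_by_id.get(s.subject_id)
        if c is None or not c.valid:
            continue
        if stages is not None and s.ajcc_stage not in stages:
            continue
        out.append(c)
    return out


def _positivity(calls: Sequence[SampleCall], marker: str) -> list[bool]:
    attr = {
        "mSEPT9": "msept9_positive",
        "mSDC2": "msdc2_positive",
        "combined": "combined_positive",
    }[marker]
    return [bool(getattr(c, attr)) for c in calls]


def evaluate_cohort(
    cohort: Cohort,
    calls: Sequence[SampleCall],
    leukocyte_levels: Sequence = (),
    ci_method: str = "wilson",
    combined_method: str = "min",
    include_na_in_test: bool = False,
) -> dict:
    """Full evaluation: per-contrast performance, ROC/AUC, level comparisons.

    Contrasts pit each case group (and the CRC stage subsets) against the
    colonoscopy-normal controls; invalid samples are excluded from every
    denominator. Returns a JSON-serializable dictionary.
    """
    calls_by_id = {c.subject_id: c for c in calls}
    controls = _calls_for(cohort, calls_by_id, "Control")
    report: dict = {"contrasts": {}, "roc": {}, "level_comparisons": {}}

    contrasts: list[tuple[str, str, tuple[str, ...] | None]] = [
        ("crc_vs_control", "CRC", None),
        ("ade_vs_control", "Ade", None),
        ("hp_vs_control", "HP", None),
        ("other_tumor_vs_control", "OtherTumor", None),
    ]
    contrasts += [
        (f"crc_{name}_vs_control", "CRC", stages)
        for name, stages in STAGE_SUBSETS.items()
    ]
    for name, group, stages in contrasts:
        cases = _calls_for(cohort, calls_by_id, group, stages)
        if not cases:
            warnings.warn(f"contrast {name}: no valid cases, omitted", stacklevel=2)
            continue
        if not controls:
            warnings.warn(f"contrast {name}: no valid controls, omitted", stacklevel=2)
            continue
        block = {}
        for marker in ("mSEPT9", "mSDC2", "combined"):
            perf = diagnostic_performance(
                _positivity(cases, marker),
                _positivity(controls, marker),
                ci_method=ci_method,
            )
            block[marker] = perf.to_dict()
        report["contrasts"][name] = block

    crc_calls = _calls_for(cohort, calls_by_id, "CRC")
    if crc_calls and controls:
        score_of = {
            "mSEPT9": lambda c: c.msept9_mean_ct,
            "mSDC2": lambda c: c.msdc2_mean_ct,
            "combined": lambda c: combined_score(
                c.msept9_mean_ct, c.msdc2_mean_ct, method=combined_method
            ),
        }
        for marker, fn in score_of.items():
            roc = roc_curve(
                [fn(c) for c in crc_calls],
                [fn(c) for c in controls],
                lower_is_disease=True,
            )
            report["roc"][marker] = roc.to_dict()

    # plasma mean-Ct comparisons, CRC against every other group
    plasma_cmp: dict = {}
    for other in ("Ade", "HP", "OtherTumor", "Control"):
        other_calls = _calls_for(cohort, calls_by_id, other)
        if not crc_calls or not other_calls:
            continue
        entry = {}
        for marker, attr in (
            ("mSEPT9", "msept9_mean_ct"),
            ("mSDC2", "msdc2_mean_ct"),
        ):
            entry[marker] = mann_whitney(
                [getattr(c, attr) for c in crc_calls],
                [getattr(c, attr) for c in other_calls],
            ).to_dict()
        plasma_cmp[f"CRC_vs_{other}"] = entry
    report["level_comparisons"]["plasma_mean_ct"] = plasma_cmp

    # leukocyte ΔCt comparisons (expected null: no group difference)
    group_of = {s.subject_id: s.group for s in cohort.subjects}
    leuko_by_group: dict[str, dict[str, list[float]]] = {}
    for lv in leukocyte_levels:
        if not lv.informative:
            continue
        g = group_of.get(lv.subject_id)
        if g is None:
            continue
        d = leuko_by_group.setdefault(g, {"mSEPT9": [], "mSDC2": []})
        d["mSEPT9"].append(lv.delta_ct_msept9)
        d["mSDC2"].append(lv.delta_ct_msdc2)
    leuko_cmp: dict = {}
    crc_levels = leuko_by_group.get("CRC")
    if crc_levels:
        for other in ("Ade", "HP", "OtherTumor", "Control"):
            other_levels = leuko_by_group.get(other)
            if not other_levels:
                continue
            leuko_cmp[f"CRC_vs_{other}"] = {
                marker: mann_whitney(
                    crc_levels[marker], other_levels[marker]
                ).to_dict()
                for marker in ("mSEPT9", "mSDC2")
            }
    report["level_comparisons"]["leukocyte_delta_ct"] = leuko_cmp

    report["stratified"] = None
    if crc_calls:
        strat = stratified_report(
            cohort, calls, include_na_in_test=include_na_in_test
        )
        report["stratified"] = {
            "rows": [
                {
                    "stratifier": r.stratifier,
                    "stratum": r.stratum,
                    "n": r.n,
                    "msept9_sensitivity_pct": r.sensitivity_pct("mSEPT9"),
                    "msdc2_sensitivity_pct": r.sensitivity_pct("mSDC2"),
                    "combined_sensitivity_pct": r.sensitivity_pct("combined"),
                }
                for r in strat.rows
            ],
            "tests": {
                name: {
                    marker: (None if t is None else t.to_dict())
                    for marker, t in by_marker.items()
                }
                for name, by_marker in strat.tests.items()
            },
        }
    return report
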