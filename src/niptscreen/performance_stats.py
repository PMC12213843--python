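"""Diagnostic-performance tables, group comparisons, and the packaged study counts.

Metrics follow the standard confusion-table definitions, reported as
percentages on the 0-100 scale with 95% confidence intervals
(Clopper-Pearson exact by default, Wilson available):

    sensitivity = TP/(TP+FN)    specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)            NPV = TN/(TN+FN)
    FPR = FP/(FP+TN)            FNR = FN/(FN+TP)

Undefined denominators are reported as not-applicable (None), never as 0.

The module also ships, as immutable checksummed package data, the confusion
counts and outcome counts of a published 60,193-pregnancy low-risk screening
cohort; :func:`reproduce_study_tables` recomputes every derived statistic
from those counts with the standard formulas and flags printed cells that the
formulas do not reproduce (they exist), rather than silently correcting
either side.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .nipt_caller import CallItem, NIPTCall
from .synthetic_cohort import (
    COMMON_TRISOMIES,
    SCA_CATEGORIES,
    KaryotypeState,
)

__all__ = [
    "ConfusionCounts",
    "PerformanceTable",
    "StudyCounts",
    "FixtureIntegrityError",
    "adjudicate",
    "call_matches_truth",
    "metrics",
    "binomial_ci",
    "bayes_ppv",
    "welch_t",
    "summarize_positive_distribution",
    "evaluate_cohort",
    "load_study_counts",
    "reproduce_study_tables",
]

#: sha256 of the packaged study-counts JSON; guards against silent edits.
_STUDY_COUNTS_SHA256 = "48f1caf2329abd2a9d18fc197b2f30b83e8230da1c48edfce982a11051c8cb82"


class FixtureIntegrityError(RuntimeError):
    """The packaged study-counts file does not match its recorded checksum."""


@dataclass
class ConfusionCounts:
    category: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion table is empty")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def binomial_ci(
    successes: int,
    trials: int,
    level: float = 0.95,
    method: str = "clopper_pearson",
) -> tuple[float, float] | None:
    """Binomial proportion CI as proportions in [0, 1].

    ``clopper_pearson`` (exact, default) or ``wilson``. Returns None for
    zero trials (not-applicable).
    """
    if trials == 0:
        return None
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method=sm_method)
    return float(lo), float(hi)


def metrics(
    counts: ConfusionCounts, ci_method: str = "clopper_pearson"
) -> dict[str, object]:
    """Derived metric set (percent scale) with 95% CIs; None where undefined."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def with_ci(num: int, den: int) -> tuple[float | None, tuple[float, float] | None]:
        if den == 0:
            return None, None
        return _ratio_pct(num, den), binomial_ci(num, den, method=ci_method)

    sens, sens_ci = with_ci(tp, tp + fn)
    spec, spec_ci = with_ci(tn, tn + fp)
    ppv, ppv_ci = with_ci(tp, tp + fp)
    npv, npv_ci = with_ci(tn, tn + fn)
    return {
        "category": counts.category,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "sensitivity_ci": sens_ci,
        "specificity": spec, "specificity_ci": spec_ci,
        "ppv": ppv, "ppv_ci": ppv_ci,
        "npv": npv, "npv_ci": npv_ci,
        "fpr": _ratio_pct(fp, fp + tn),
        "fnr": _ratio_pct(fn, fn + tp),
    }


def bayes_ppv(sensitivity: float, fpr: float, prevalence: float) -> float | None:
    """Expected PPV of a screen from sensitivity, FPR, and prevalence (all in [0,1])."""
    for name, v in (("sensitivity", sensitivity), ("fpr", fpr), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    num = sensitivity * prevalence
    den = num + fpr * (1.0 - prevalence)
    if den == 0.0:
        return None if num == 0.0 and prevalence > 0.0 else 0.0
    return num / den


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t-test: (t, degrees of freedom, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0.0:
        df = float(len(a) + len(b) - 2)
        return 0.0, df, 1.0
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------


def _item_matches_truth(item: CallItem, truth: KaryotypeState) -> bool:
    """Category-level concordance of one positive finding with the fetal truth.

    Common trisomies and SCA subtypes must match exactly; an RAA call matches
    when the chromosome agrees, regardless of mosaic fraction or direction; a
    CNV call matches any overlapping true segment in the same direction.
    """
    cat = truth.category
    if item.category in COMMON_TRISOMIES or item.category in SCA_CATEGORIES:
        return item.category == cat
    if item.category == "RAA":
        return cat == "RAA" and item.chrom == truth.raa_chrom
    if item.category == "CNV":
        if cat != "CNV":
            return False
        chrom, start, end, cn = truth.cnv_segment
        truth_dir = "dup" if cn == 3 else "del"
        if item.chrom != chrom or item.kind != truth_dir:
            return False
        s, e = item.segment
        return s < end and start < e
    return False


def call_matches_truth(call: NIPTCall, truth: KaryotypeState) -> bool:
    """Whether any finding of a positive call is concordant with the fetal truth."""
    return any(_item_matches_truth(item, truth) for item in call.calls)


def adjudicate(call: NIPTCall, fetal_truth: KaryotypeState) -> list[tuple[str, str]]:
    """Per-finding adjudication of one resolved call against the fetal truth.

    Returns (category, label) pairs: each positive finding is a TP or FP of
    its called category; a negative call is one TN (category ``EUPLOID``) or
    one FN attributed to the truth category. No-calls are excluded upstream.
    """
    if call.result == "no_call":
        raise ValueError("no_call results are excluded from adjudication")
    if call.result == "negative":
        if fetal_truth.is_abnormal:
            return [(fetal_truth.category, "FN")]
        return [("EUPLOID", "TN")]
    return [
        (item.category, "TP" if _item_matches_truth(item, fetal_truth) else "FP")
        for item in call.calls
    ]


@dataclass
class PerformanceTable:
    """Per-category confusion counts plus derived metrics (Table-2 shaped)."""

    rows: dict[str, ConfusionCounts]
    ci_method: str = "clopper_pearson"
    discrepancies: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for counts in self.rows.values():
            m = metrics(counts, ci_method=self.ci_method)
            rec = {
                "category": m["category"],
                "positive": counts.tp + counts.fp,
                "tp": m["tp"], "fp": m["fp"], "tn": m["tn"], "fn": m["fn"],
            }
            for key in ("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr"):
                v = m[key]
                rec[key] = None if v is None else round(v, 2)
                ci = m.get(f"{key}_ci")
                if ci is not None:
                    rec[f"{key}_low"], rec[f"{key}_high"] = round(ci[0], 4), round(ci[1], 4)
            records.append(rec)
        return pd.DataFrame(records)

    def metric(self, category: str, name: str) -> float | None:
        v = metrics(self.rows[category], ci_method=self.ci_method)[name]
        return None if v is None else round(v, 2)


_TOP_CATEGORIES = ("T21", "T18", "T13", "SCAs", "RAAs", "CNVs")


def _category_rollup(category: str) -> str:
    """Map a per-call category to its Table-2 top-level row label."""
    if category in SCA_CATEGORIES:
        return "SCAs"
    if category == "RAA":
        return "RAAs"
    if category == "CNV":
        return "CNVs"
    return category


def evaluate_cohort(
    calls: Sequence[NIPTCall],
    truths: Sequence[KaryotypeState],
    ci_method: str = "clopper_pearson",
) -> PerformanceTable:
    """Confusion tables per category for a screened cohort.

    Pooling is per finding: a pregnancy with two concordant/discordant
    findings contributes one count per finding. No-calls are excluded from
    every denominator. Category TN counts are completed as
    ``n_evaluated - TP - FP - FN`` per category.
    """
    if len(calls) != len(truths):
        raise ValueError("calls and truths differ in length")
    labels: dict[str, dict[str, int]] = {}
    n_eval = 0
    total = {"TP": 0, "FP": 0, "FN": 0}
    for call, truth in zip(calls, truths):
        if call.result == "no_call":
            continue
        n_eval += 1
        for category, label in adjudicate(call, truth):
            if label == "TN":
                continue
            top = _category_rollup(category)
            for key in {top, category} if category != top else {top}:
                labels.setdefault(key, {"TP": 0, "FP": 0, "FN": 0})[label] += 1
            total[label] += 1

    rows: dict[str, ConfusionCounts] = {}
    ordered = [c for c in (*_TOP_CATEGORIES, *SCA_CATEGORIES) if c in labels]
    ordered += [c for c in labels if c not in ordered]
    for cat in ordered:
        c = labels[cat]
        tn = n_eval - c["TP"] - c["FP"] - c["FN"]
        rows[cat] = ConfusionCounts(cat, tp=c["TP"], fp=c["FP"], tn=max(tn, 0), fn=c["FN"])
    tn_total = n_eval - total["TP"] - total["FP"] - total["FN"]
    rows["Total"] = ConfusionCounts(
        "Total", tp=total["TP"], fp=total["FP"], tn=max(tn_total, 0), fn=total["FN"]
    )
    return PerformanceTable(rows=rows, ci_method=ci_method)


def summarize_positive_distribution(
    positive_counts: Mapping[str, int] | Iterable[str],
) -> dict[str, float]:
    """Share of screen positives per category, percentages summing to ~100.

    Accepts either a category -> count mapping or an iterable of category
    labels (one per positive call).
    """
    if not isinstance(positive_counts, Mapping):
        tally: dict[str, int] = {}
        for cat in positive_counts:
            tally[cat] = tally.get(cat, 0) + 1
        positive_counts = tally
    total = sum(positive_counts.values())
    if total == 0:
        return {}
    return {
        cat: round(100.0 * n / total, 2)
        for cat, n in sorted(positive_counts.items(), key=lambda kv: -kv[1])
    }


# ---------------------------------------------------------------------------
# Packaged study counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyCounts:
    """Verbatim published counts: confusion tables, outcome cascade, totals."""

    cohort: dict
    performance: dict
    positive_distribution: dict
    raa: dict
    outcomes: dict
    fetal_fraction: dict


def load_study_counts() -> StudyCounts:
    """Load and checksum-verify the packaged study counts."""
    ref = resources.files("niptscreen").joinpath("data/study_counts.json")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _STUDY_COUNTS_SHA256:
        raise FixtureIntegrityError(
            f"study_counts.json checksum mismatch: {digest} != {_STUDY_COUNTS_SHA256}"
        )
    data = json.loads(raw)
    return StudyCounts(
        cohort=data["cohort"],
        performance=data["performance"],
        positive_distribution=data["positive_distribution"],
        raa=data["raa"],
        outcomes=data["outcomes"],
        fetal_fraction=data["fetal_fraction"],
    )


def reproduce_study_tables(counts: StudyCounts | None = None) -> dict:
    """Recompute the published performance/outcome/distribution statistics.

    Every derived value comes from the stored counts via the standard
    formulas at 2 dp; printed cells that disagree with the formulas are
    listed under ``discrepancies`` (printed verbatim vs computed), never
    overwritten.
    """
    counts = counts or load_study_counts()
    rows: dict[str, ConfusionCounts] = {}
    discrepancies: list[str] = []
    for cat, row in counts.performance.items():
        cc = ConfusionCounts(cat, tp=row["tp"], fp=row["fp"], tn=row["tn"], fn=row["fn"])
        rows[cat] = cc
        m = metrics(cc)
        for key in ("sensitivity", "specificity", "ppv", "npv", "fpr", "fnr"):
            printed = row["printed"][key]
            computed = m[key]
            if computed is not None and abs(round(computed, 2) - printed) > 0.005:
                discrepancies.append(
                    f"{cat}.{key}: printed {printed:.2f} vs computed {round(computed, 2):.2f}"
                )
    table = PerformanceTable(rows=rows, discrepancies=discrepancies)

    dist = summarize_positive_distribution(counts.positive_distribution)
    cohort = counts.cohort
    positivity = round(100.0 * cohort["n_positive"] / cohort["n_low_risk"], 2)

    outcome_summary: dict[str, dict[str, float | None]] = {}
    for group, branches in counts.outcomes.items():
        if group == "total":
            continue
        summary = {}
        for branch, row in branches.items():
            summary[f"{branch}_termination_pct"] = (
                None if row["n"] == 0 else round(100.0 * row["termination"] / row["n"], 2)
            )
        outcome_summary[group] = summary

    raa = counts.raa
    headline = {
        "total_ppv_pct": table.metric("Total", "ppv"),
        "total_fpr_pct": table.metric("Total", "fpr"),
        "total_sensitivity_pct": table.metric("Total", "sensitivity"),
        "positivity_pct": positivity,
        "raa_tp_chr16_share_pct": round(100.0 * raa["tp_chr16"] / raa["n_true_positive"], 2),
        "sca_tp_termination_pct": outcome_summary["SCA"]["TP_termination_pct"],
        "amniocentesis_uptake_pct": round(
            100.0 * cohort["n_amniocentesis"] / cohort["n_positive"], 2
        ),
        "amnio_confirmation_pct": round(
            100.0 * cohort["n_confirmed_by_amnio"] / cohort["n_amniocentesis"], 2
        ),
    }
    return {
        "performance": table,
        "positive_distribution": dist,
        "positivity_pct": positivity,
        "outcomes": outcome_summary,
        "headline": headline,
        "discrepancies": discrepancies,
    }
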