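"""End-to-end pipeline: correction, classification, group summaries, test battery.

Reads a nodule-level cohort, fills the tissue-fraction-corrected SUVmax and
both positivity flags on every record, builds per-group and pooled
summaries shaped like the study's characteristics table, and runs the full
comparison battery:

* Kruskal-Wallis across pathological groups for size, HU, SUVmax, SUVmaxTF;
* Freeman-Halton exact tests for the visual and semiquantitative
  positivity rates across groups;
* pairwise post-hoc exact tests with Bonferroni adjustment (raw p also
  reported — small-sample studies commonly print the unadjusted value);
* Wilcoxon signed-rank for the SUVmax shift under correction and exact
  McNemar for the change in positivity at the 2.5 cutoff;
* the percent change of the pooled median SUVmax.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import NoduleRecord
from .correction import CorrectionParams, SuvMeasurement, classify_positivity, correct_suv
from .stats import (
    ContingencyTable,
    PairedBinary,
    TestResult,
    bonferroni_posthoc,
    fisher_exact,
    kruskal_wallis,
    mcnemar_exact,
    median_quartiles,
    wilcoxon_signed_rank,
)

__all__ = ["GroupSummary", "AnalysisReport", "run_pipeline", "summarize_group", "render_text_table"]

_SUMMARY_VARS = ("size_mm", "hu_ggn", "suv_max", "suv_max_tf")


@dataclass(frozen=True)
class GroupSummary:
    """One column of the characteristics table: summaries for one group."""

    pathology: str
    n: int
    quartiles: Dict[str, Tuple[float, float, float]]  # var -> (median, q1, q3)
    visual_positive_n: Optional[int]
    visual_n: int  # records with a visual read (missing reads excluded pairwise)
    positive_before_n: int
    positive_after_n: int

    @property
    def visual_rate(self) -> Optional[float]:
        if self.visual_positive_n is None or self.visual_n == 0:
            return None
        return self.visual_positive_n / self.visual_n

    @property
    def positive_before_rate(self) -> float:
        return self.positive_before_n / self.n

    @property
    def positive_after_rate(self) -> float:
        return self.positive_after_n / self.n

    def to_dict(self) -> Dict:
        return {
            "pathology": self.pathology,
            "n": self.n,
            "quartiles": {k: list(v) for k, v in self.quartiles.items()},
            "visual_positive_n": self.visual_positive_n,
            "visual_n": self.visual_n,
            "visual_rate": self.visual_rate,
            "positive_before_n": self.positive_before_n,
            "positive_before_rate": self.positive_before_rate,
            "positive_after_n": self.positive_after_n,
            "positive_after_rate": self.positive_after_rate,
        }


@dataclass
class AnalysisReport:
    """Structured output of the full analysis."""

    group_summaries: List[GroupSummary]
    pooled_summary: GroupSummary
    group_tests: Dict[str, TestResult]
    posthoc_visual: Dict[str, Dict]
    paired_wilcoxon: TestResult
    paired_mcnemar: TestResult
    percent_change_median_suv: float

    @property
    def percent_change_display(self) -> int:
        """Percent change of the pooled median SUVmax, rounded for display."""
        return int(round(self.percent_change_median_suv))

    def to_dict(self) -> Dict:
        return {
            "groups": [g.to_dict() for g in self.group_summaries],
            "pooled": self.pooled_summary.to_dict(),
            "group_tests": {k: t.to_dict() for k, t in self.group_tests.items()},
            "posthoc_visual": self.posthoc_visual,
            "paired": {
                "wilcoxon_suv_shift": self.paired_wilcoxon.to_dict(),
                "mcnemar_positivity": self.paired_mcnemar.to_dict(),
            },
            "percent_change_median_suv": self.percent_change_median_suv,
            "percent_change_display": self.percent_change_display,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _apply_correction(records: Sequence[NoduleRecord], params: CorrectionParams) -> None:
    for rec in records:
        rec.validate(hu_air=params.hu_air, hu_tissue=params.hu_tissue)
        corrected = correct_suv(SuvMeasurement(rec.suv_max, rec.hu_ggn), params)
        rec.suv_max_tf = corrected.suv_max_tf
        rec.semiquant_positive_before = classify_positivity(rec.suv_max, params)
        rec.semiquant_positive_after = classify_positivity(rec.suv_max_tf, params)


def summarize_group(
    records: Sequence[NoduleRecord],
    params: CorrectionParams = CorrectionParams(),
    label: Optional[str] = None,
) -> GroupSummary:
    """Median (Q1-Q3) and positivity counts for one group of corrected records."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty group")
    if any(r.suv_max_tf is None for r in records):
        _apply_correction(records, params)
    quartiles = {
        var: median_quartiles([getattr(r, var) for r in records]) for var in _SUMMARY_VARS
    }
    with_read = [r for r in records if r.visual_positive is not None]
    return GroupSummary(
        pathology=label if label is not None else records[0].pathology,
        n=len(records),
        quartiles=quartiles,
        visual_positive_n=sum(r.visual_positive for r in with_read) if with_read else None,
        visual_n=len(with_read),
        positive_before_n=sum(r.semiquant_positive_before for r in records),
        positive_after_n=sum(r.semiquant_positive_after for r in records),
    )


def _positivity_table(summaries: Sequence[GroupSummary], kind: str) -> ContingencyTable:
    rows = []
    for s in summaries:
        if kind == "visual":
            pos, total = (s.visual_positive_n or 0), s.visual_n
        elif kind == "before":
            pos, total = s.positive_before_n, s.n
        else:
            pos, total = s.positive_after_n, s.n
        rows.append([pos, total - pos])
    return ContingencyTable(
        counts=np.array(rows),
        row_labels=[s.pathology for s in summaries],
        col_labels=["positive", "negative"],
    )


def run_pipeline(
    cohort: Sequence[NoduleRecord], params: CorrectionParams = CorrectionParams()
) -> AnalysisReport:
    """Run the full correction + positivity analysis on a cohort.

    Mutates the records in place (fills ``suv_max_tf`` and both positivity
    flags), then computes every summary and test.  Any record violating its
    invariants aborts the run, naming the offending nodule.
    """
    records = list(cohort)
    if not records:
        raise ValueError("cohort is empty")
    _apply_correction(records, params)

    order = list(dict.fromkeys(r.pathology for r in records))
    by_group = {g: [r for r in records if r.pathology == g] for g in order}
    summaries = [summarize_group(by_group[g], params) for g in order]
    pooled = summarize_group(records, params, label="total")

    # across-group tests (Table-2-shaped rows)
    group_tests: Dict[str, TestResult] = {}
    multi = len(order) >= 2
    for var in _SUMMARY_VARS:
        if multi:
            group_tests[f"kruskal_{var}"] = kruskal_wallis(
                [[getattr(r, var) for r in by_group[g]] for g in order]
            )
    if multi:
        visual_summaries = [s for s in summaries if s.visual_n > 0]
        if len(visual_summaries) >= 2:
            group_tests["fisher_visual"] = fisher_exact(
                _positivity_table(visual_summaries, "visual")
            )
        group_tests["fisher_positive_before"] = fisher_exact(
            _positivity_table(summaries, "before")
        )
        group_tests["fisher_positive_after"] = fisher_exact(
            _positivity_table(summaries, "after")
        )

    # pairwise post-hoc on visual positivity, raw and Bonferroni-adjusted
    posthoc: Dict[str, Dict] = {}
    pairs = [
        (a, b)
        for a, b in itertools.combinations(order, 2)
        if by_group[a] and by_group[b]
    ]
    raw_ps, pair_names = [], []
    for a, b in pairs:
        sa = summarize_group(by_group[a], params)
        sb = summarize_group(by_group[b], params)
        if sa.visual_n == 0 or sb.visual_n == 0:
            continue
        res = fisher_exact(_positivity_table([sa, sb], "visual"))
        pair_names.append(f"{a}_vs_{b}")
        raw_ps.append(res.p_value)
    adjusted = bonferroni_posthoc(raw_ps) if raw_ps else []
    for name, raw, adj in zip(pair_names, raw_ps, adjusted):
        posthoc[name] = {"p_raw": raw, "p_bonferroni": adj}

    # paired before/after analysis
    before = [r.suv_max for r in records]
    after = [r.suv_max_tf for r in records]
    wilcoxon = wilcoxon_signed_rank(before, after)
    b = sum(
        r.semiquant_positive_before and not r.semiquant_positive_after for r in records
    )
    c = sum(
        r.semiquant_positive_after and not r.semiquant_positive_before for r in records
    )
    mcnemar = mcnemar_exact(PairedBinary(b=b, c=c, n_concordant=len(records) - b - c))

    med_before = pooled.quartiles["suv_max"][0]
    med_after = pooled.quartiles["suv_max_tf"][0]
    percent_change = 100.0 * (med_after - med_before) / med_before

    return AnalysisReport(
        group_summaries=summaries,
        pooled_summary=pooled,
        group_tests=group_tests,
        posthoc_visual=posthoc,
        paired_wilcoxon=wilcoxon,
        paired_mcnemar=mcnemar,
        percent_change_median_suv=percent_change,
    )


def render_text_table(report: AnalysisReport) -> str:
    """Plain-text rendering of the report in the study table's layout."""
    cols = report.group_summaries + [report.pooled_summary]
    header = ["Characteristic"] + [f"{s.pathology} (n={s.n})" for s in cols] + ["p"]

    def mq(s: GroupSummary, var: str, nd: int = 1) -> str:
        med, q1, q3 = s.quartiles[var]
        return f"{med:.{nd}f} ({q1:.{nd}f}-{q3:.{nd}f})"

    def rate(num: Optional[int], den: int) -> str:
        if num is None or den == 0:
            return "-"
        return f"{num} ({100 * num / den:.0f}%)"

    def p_str(key: str) -> str:
        t = report.group_tests.get(key)
        return f"{t.p_value:.3f}" if t else "-"

    rows = [
        ["Size of nodule, mm"] + [mq(s, "size_mm") for s in cols] + [p_str("kruskal_size_mm")],
        ["Hounsfield unit"] + [mq(s, "hu_ggn", 0) for s in cols] + [p_str("kruskal_hu_ggn")],
        ["Visual analysis positive"]
        + [rate(s.visual_positive_n, s.visual_n) for s in cols]
        + [p_str("fisher_visual")],
        ["SUVmax"] + [mq(s, "suv_max") for s in cols] + [p_str("kruskal_suv_max")],
        ["SUVmaxTF"] + [mq(s, "suv_max_tf") for s in cols] + [p_str("kruskal_suv_max_tf")],
        ["SUVmax >= cutoff"]
        + [rate(s.positive_before_n, s.n) for s in cols]
        + [p_str("fisher_positive_before")],
        ["SUVmaxTF >= cutoff"]
        + [rate(s.positive_after_n, s.n) for s in cols]
        + [p_str("fisher_positive_after")],
    ]
    table = [header] + rows
    widths = [max(len(row[j]) for row in table) for j in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in table]
    lines.insert(1, "-" * len(lines[0]))
    lines.append(
        f"Pooled median SUVmax change after correction: "
        f"{report.percent_change_display}% "
        f"(Wilcoxon p = {report.paired_wilcoxon.p_value:.2e}; "
        f"McNemar p = {report.paired_mcnemar.p_value:.2e})"
    )
    return "\n".join(lines)
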