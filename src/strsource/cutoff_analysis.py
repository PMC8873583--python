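"""ROC/AUC analysis, per-cutoff sensitivity/specificity/Youden tables, and
group-difference tests for the allele-sharing statistics.

Positives are paired-carcinoma (PC) scores; negatives are one of the UI,
FS or PO comparison groups.  A1, A2 and the IBS score are oriented
high-is-positive (decision rule "statistic >= c -> same source"); A0 is
inverted (a low A0 supports common source), so all four statistics share
one code path.  Youden's index, in percentage points, is
sensitivity + specificity - 100; the optimal cutoff maximizes it, with
ties broken toward the smallest cutoff (which maximizes sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._common import round_half_up
from .ibs_scoring import IBSResult

__all__ = [
    "STATISTICS",
    "ORIENTATIONS",
    "CutoffRow",
    "RocSummary",
    "sens_spec_at_cutoff",
    "youden",
    "auc",
    "cutoff_table",
    "best_cutoff",
    "roc_summary",
    "analyze_groups",
    "AnalysisResult",
    "group_difference_test",
    "recommend",
    "load_reference_cutoff_table",
    "reference_rows",
]

STATISTICS = ("A0", "A1", "A2", "IBS")
CONTRASTS = ("UI", "FS", "PO")

#: Decision orientation per statistic: "high" means larger values support
#: the pair being same-source (PC); "low" the opposite.
ORIENTATIONS: dict[str, str] = {
    "A0": "low", "A1": "high", "A2": "high", "IBS": "high",
}

#: Default interpretive A2 thresholds: at or above the first the pair is
#: unlikely to be unrelated; at or above the second the tumor plausibly
#: comes from the matched individual.
DEFAULT_RECOMMEND_THRESHOLDS: tuple[int, int] = (13, 18)


def _passes(score: float, c: float, orientation: str) -> bool:
    if orientation == "high":
        return score >= c
    if orientation == "low":
        return score <= c
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class CutoffRow:
    """Sensitivity/specificity/Youden (percent) at one integer cutoff.

    Values are stored at full precision; :meth:`rounded` renders the
    2-decimal half-up display form.
    """

    cutoff: int
    sensitivity: float
    specificity: float
    youden: float

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage {v} outside [0, 100]")
        if not math.isclose(self.youden,
                            self.sensitivity + self.specificity - 100.0,
                            abs_tol=1e-9):
            raise ValueError("Youden's index inconsistent with sens/spec")

    def rounded(self) -> dict[str, float]:
        return {
            "cutoff": self.cutoff,
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "youden": round_half_up(self.youden),
        }


def sens_spec_at_cutoff(
    pos: Sequence[float],
    neg: Sequence[float],
    c: float,
    orientation: str = "high",
) -> tuple[float, float]:
    """Empirical sensitivity and specificity (percent, full precision)."""
    if not len(pos) or not len(neg):
        raise ValueError("score lists must be non-empty")
    sens = 100.0 * sum(_passes(s, c, orientation) for s in pos) / len(pos)
    spec = 100.0 * sum(not _passes(s, c, orientation) for s in neg) / len(neg)
    return sens, spec


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's index in percentage points."""
    if not (0.0 <= sensitivity <= 100.0 and 0.0 <= specificity <= 100.0):
        raise ValueError("sensitivity/specificity must lie in [0, 100]")
    return sensitivity + specificity - 100.0


def auc(
    pos: Sequence[float], neg: Sequence[float], orientation: str = "high"
) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2).

    The rank-sum formulation, equal to the trapezoidal area under the
    empirical ROC curve.
    """
    if not len(pos) or not len(neg):
        raise ValueError("score lists must be non-empty")
    scores = np.concatenate([np.asarray(pos, float), np.asarray(neg, float)])
    if orientation == "low":
        scores = -scores
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    if np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(labels, scores))


def cutoff_table(
    pos: Sequence[float],
    neg: Sequence[float],
    cutoffs: Sequence[int],
    orientation: str = "high",
) -> list[CutoffRow]:
    rows = []
    for c in cutoffs:
        sens, spec = sens_spec_at_cutoff(pos, neg, c, orientation)
        rows.append(CutoffRow(int(c), sens, spec, youden(sens, spec)))
    return rows


def best_cutoff(rows: Sequence[CutoffRow]) -> tuple[int, float]:
    """The cutoff maximizing Youden's index; ties go to the smallest cutoff."""
    if not rows:
        raise ValueError("no cutoff rows")
    best = min(rows, key=lambda r: (-r.youden, r.cutoff))
    return best.cutoff, best.youden


@dataclass
class RocSummary:
    """ROC/cutoff analysis of one statistic against one comparison group."""

    statistic: str
    group: str
    auc: float
    rows: list[CutoffRow]
    best: tuple[int, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.rounded() for r in self.rows])


def roc_summary(
    statistic: str,
    group: str,
    pos: Sequence[float],
    neg: Sequence[float],
    max_cutoff: int,
) -> RocSummary:
    orientation = ORIENTATIONS[statistic]
    rows = cutoff_table(pos, neg, range(1, max_cutoff + 1), orientation)
    return RocSummary(
        statistic=statistic, group=group,
        auc=auc(pos, neg, orientation), rows=rows, best=best_cutoff(rows),
    )


@dataclass
class AnalysisResult:
    """All ROC summaries plus PC-vs-group t-tests for one scored cohort."""

    summaries: dict[tuple[str, str], RocSummary]
    tests: dict[tuple[str, str], tuple[float, float]]
    panel_size: int

    def cutoff_frame(self, statistic: str) -> pd.DataFrame:
        """Tabular layout: cutoff, then sens/spec/youden per group."""
        out = {}
        for group in CONTRASTS:
            s = self.summaries[(statistic, group)]
            rows = [r.rounded() for r in s.rows]
            out.setdefault("cutoff", [r["cutoff"] for r in rows])
            key = group.lower()
            out[f"{key}_sensitivity"] = [r["sensitivity"] for r in rows]
            out[f"{key}_specificity"] = [r["specificity"] for r in rows]
            out[f"{key}_youden"] = [r["youden"] for r in rows]
        return pd.DataFrame(out)


def analyze_groups(
    results: Mapping[str, Sequence[IBSResult]],
    panel_size: int,
    welch: bool = True,
) -> AnalysisResult:
    """Run the full cutoff/ROC/t-test analysis over scored groups.

    Positives are the PC results; each of UI, FS, PO in turn supplies the
    negatives.  A-statistics are tabulated at integer cutoffs
    1..panel_size, the IBS score at 1..2*panel_size.  No multiple-testing
    correction is applied to the group-difference t-tests (raw p-values
    are reported).
    """
    if "PC" not in results or not results["PC"]:
        raise ValueError("PC group is required as the positive class")
    values = {
        group: {
            stat: [getattr(r, stat.lower()) for r in results[group]]
            for stat in STATISTICS
        }
        for group in results
    }
    summaries = {}
    tests = {}
    for stat in STATISTICS:
        max_cutoff = 2 * panel_size if stat == "IBS" else panel_size
        for group in CONTRASTS:
            if group not in results or not results[group]:
                continue
            summaries[(stat, group)] = roc_summary(
                stat, group, values["PC"][stat], values[group][stat],
                max_cutoff,
            )
            tests[(stat, group)] = group_difference_test(
                values["PC"][stat], values[group][stat], welch=welch,
            )
    return AnalysisResult(summaries=summaries, tests=tests,
                          panel_size=panel_size)


def group_difference_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test (Welch by default, pooled-variance otherwise).

    Degenerate inputs follow the convention: both groups constant with
    equal means -> (0, 1); constant with different means -> (inf, 0).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def recommend(
    result: IBSResult | int,
    thresholds: tuple[int, int] = DEFAULT_RECOMMEND_THRESHOLDS,
) -> dict:
    """Heuristic source-attribution verdict from a pair's A2 count.

    Applies the two configured A2 thresholds: at or above the lower the
    pair is unlikely to be unrelated; at or above the upper the tumor is
    consistent with coming from the matched individual.  Always labelled
    heuristic — thresholds derive from one study design and panel.
    """
    a2 = result.a2 if isinstance(result, IBSResult) else int(result)
    t_unrelated, t_same = thresholds
    if t_unrelated > t_same:
        raise ValueError("unrelated-exclusion threshold exceeds same-source")
    if a2 >= t_same:
        verdict = f"consistent with same-source (A2 >= {t_same})"
    elif a2 >= t_unrelated:
        verdict = (
            f"unlikely unrelated (A2 >= {t_unrelated}), "
            f"below same-source threshold {t_same}"
        )
    else:
        verdict = "no support for common source"
    return {
        "a2": a2,
        "thresholds": {"unrelated_exclusion": t_unrelated,
                       "same_source": t_same},
        "verdict": verdict,
        "note": "heuristic rule; thresholds assume a 27-locus autosomal "
                "panel scored under the analytical threshold",
    }


def load_reference_cutoff_table() -> pd.DataFrame:
    """The published A2 cutoff table (sens/spec/Youden per group) as printed."""
    with resources.files("strsource.data").joinpath(
        "a2_cutoff_reference.tsv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def reference_rows(group: str) -> list[CutoffRow]:
    """Reconstruct :class:`CutoffRow` objects from the published columns.

    Youden is recomputed from the printed sensitivity/specificity rather
    than read from the table, so the rows stay internally consistent.
    """
    df = load_reference_cutoff_table()
    key = group.lower()
    return [
        CutoffRow(
            int(r["cutoff"]),
            float(r[f"{key}_sensitivity"]),
            float(r[f"{key}_specificity"]),
            youden(float(r[f"{key}_sensitivity"]),
                   float(r[f"{key}_specificity"])),
        )
        for _, r in df.iterrows()
    ]
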