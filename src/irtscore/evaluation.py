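"""Severity-group discrimination of scoring methods: ANOVA F and relative
precision.

Scores from each method are compared across the clinician-assigned severity
groups (none / mild / moderate / severe) with a one-way fixed-effects ANOVA
(overall) and equal-variance two-group F statistics (pairwise; the square of
the independent-samples t). The relative precision (RP) of a method against
the unweighted reference is the ratio of their F statistics for the same
comparison: RP > 1 means the method separates the severity groups more
sharply than unweighted sum scoring. RP is invariant to rescaling a method's
scores, which is what makes scores on different metrics comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEVERITY_ORDER",
    "EvaluationTable",
    "group_summary",
    "anova_f",
    "pairwise_f",
    "relative_precision",
    "bonferroni_adjust",
    "build_evaluation_table",
]

SEVERITY_ORDER = ("none", "mild", "moderate", "severe")
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def _group_arrays(
    scores: np.ndarray, labels: Sequence[str]
) -> dict[str, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    out = {}
    for level in SEVERITY_ORDER:
        vals = scores[labels == level]
        if vals.size:
            out[level] = vals
    if len(out) < 2:
        raise ValueError("need at least two non-empty severity groups")
    return out


def group_summary(scores: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Mean, SE (sd/sqrt(n)) and n per severity group, plus pairwise mean
    differences (higher-severity mean minus lower)."""
    groups = _group_arrays(scores, labels)
    rows = []
    for level, vals in groups.items():
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append({"group": level, "n": vals.size, "mean": float(vals.mean()), "se": se})
    frame = pd.DataFrame(rows).set_index("group")
    present = [g for g in SEVERITY_ORDER if g in groups]
    for i, j in PAIRS:
        gi, gj = SEVERITY_ORDER[i], SEVERITY_ORDER[j]
        if gi in groups and gj in groups:
            frame.loc[gi, f"diff_vs_{gj}"] = groups[gj].mean() - groups[gi].mean()
    return frame


def anova_f(
    scores: np.ndarray, labels: Sequence[str]
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    groups = list(_group_arrays(scores, labels).values())
    k = len(groups)
    n = sum(g.size for g in groups)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        if ss_between > 0.0:
            return float("inf"), df1, df2, 0.0
        return 0.0, df1, df2, 1.0
    F = (ss_between / df1) / (ss_within / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def pairwise_f(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-group one-way F: the square of the equal-variance t statistic."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    scores = np.concatenate([a, b])
    k = 2
    grand = scores.mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df2 = scores.size - k
    if ss_within == 0.0:
        return float("inf") if ss_between > 0 else 0.0
    return float(ss_between / (ss_within / df2))


def relative_precision(f_method: float, f_reference: float) -> float:
    """RP = F_method / F_reference (undefined for a zero reference F)."""
    if f_reference == 0.0:
        raise ValueError("reference F statistic is zero; RP undefined")
    if f_reference < 0.0:
        raise ValueError("F statistics are non-negative")
    return float(f_method) / float(f_reference)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni: p_adj = min(1, m * p); default m = number of p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("m must be at least 1")
    return np.minimum(1.0, m * p)


@dataclass
class EvaluationTable:
    """Severity-group comparison of several scoring methods.

    ``frame`` is the long layout (one row per method x quantity with group
    and pairwise columns); the reference method's RP entries are identically
    1. ``to_text`` renders an aligned facsimile.
    """

    frame: pd.DataFrame
    reference: str
    group_sizes: dict[str, int]

    def to_text(self) -> str:
        lines = []
        hdr = (
            ["Method", "Qty"]
            + [f"{g}(n={self.group_sizes.get(g, 0)})" for g in SEVERITY_ORDER]
            + ["overall"]
            + [f"{i}v{j}" for i, j in PAIRS]
        )
        widths = [22, 10] + [14] * len(SEVERITY_ORDER) + [10] * 7
        lines.append("".join(h.ljust(w) for h, w in zip(hdr, widths)))
        for _, row in self.frame.iterrows():
            cells = [str(row["method"]), str(row["quantity"])]
            for col in list(SEVERITY_ORDER) + ["overall"] + [
                f"d{i}{j}" for i, j in PAIRS
            ]:
                v = row.get(col)
                cells.append("" if pd.isna(v) else f"{v:.3f}")
            lines.append("".join(c.ljust(w) for c, w in zip(cells, widths)))
        return "\n".join(lines)


def build_evaluation_table(
    score_sets: Mapping[str, np.ndarray],
    severity_labels: Sequence[str],
    reference_method: str = "unweighted",
    bonferroni_m: int = 6,
) -> EvaluationTable:
    """Assemble the full comparison: means (SE), mean differences, overall and
    pairwise F, raw and Bonferroni-adjusted overall p, and RP against the
    reference method.

    All methods must be scored on the same respondents (equal-length score
    vectors, aligned with ``severity_labels``).
    """
    if reference_method not in score_sets:
        raise ValueError(f"reference method {reference_method!r} not in score sets")
    labels = np.asarray(severity_labels, dtype=object)
    n = labels.size
    for method, scores in score_sets.items():
        if np.asarray(scores).size != n:
            raise ValueError(
                f"method {method!r} scored {np.asarray(scores).size} respondents, "
                f"expected {n}"
            )
    groups_ref = _group_arrays(np.asarray(score_sets[reference_method]), labels)
    group_sizes = {g: v.size for g, v in groups_ref.items()}

    stats_by_method: dict[str, dict[str, float]] = {}
    rows = []
    for method, scores in score_sets.items():
        scores = np.asarray(scores, dtype=float)
        groups = _group_arrays(scores, labels)
        F_overall, df1, df2, p_overall = anova_f(scores, labels)
        fs: dict[str, float] = {"overall": F_overall}
        mean_row = {"method": method, "quantity": "mean"}
        se_row = {"method": method, "quantity": "se"}
        diff_row = {"method": method, "quantity": "mean_diff"}
        f_row = {"method": method, "quantity": "F"}
        for g, vals in groups.items():
            mean_row[g] = vals.mean()
            se_row[g] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        for i, j in PAIRS:
            gi, gj = SEVERITY_ORDER[i], SEVERITY_ORDER[j]
            if gi in groups and gj in groups:
                key = f"d{i}{j}"
                diff_row[key] = groups[gj].mean() - groups[gi].mean()
                fs[key] = pairwise_f(groups[gi], groups[gj])
                f_row[key] = fs[key]
        f_row["overall"] = F_overall
        f_row["p_overall"] = p_overall
        f_row["p_overall_bonferroni"] = float(bonferroni_adjust([p_overall], bonferroni_m)[0])
        stats_by_method[method] = fs
        rows += [mean_row, se_row, diff_row, f_row]

    ref_fs = stats_by_method[reference_method]
    for method in score_sets:
        rp_row = {"method": method, "quantity": "RP"}
        for key, f_val in stats_by_method[method].items():
            rp_row[key] = relative_precision(f_val, ref_fs[key])
        rows.append(rp_row)

    frame = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(score_sets)}
    qorder = {"mean": 0, "se": 1, "mean_diff": 2, "F": 3, "RP": 4}
    frame = frame.sort_values(
        by=["method", "quantity"],
        key=lambda col: col.map(order) if col.name == "method" else col.map(qorder),
        kind="stable",
    ).reset_index(drop=True)
    return EvaluationTable(frame=frame, reference=reference_method, group_sizes=group_sizes)
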