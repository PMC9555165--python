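"""IRT-based weighted sum scores on the 0-81 metric.

Under the GRM, an endorsed category's weight is the product of the item's
discrimination and the endorsed category's threshold, ``a_i * b_ik`` (the
no-symptom category carries weight 0). The raw weighted sum over the nine
items is divided by its plausible maximum - the score of a respondent
endorsing every item's top category, ``sum_i a_i * b_i6`` - and multiplied by
81 so weighted and unweighted totals share a scale.

Under the NRM, the weight of combination category ``sf`` is
``a_i(sf) + c_i(sf)`` (0 for the reference category); the plausible maximum
sums each item's largest category weight. NRM weights can be negative (the
published calibration contains negative slopes and intercepts), so NRM raw
and rescaled scores may legitimately fall below 0; nothing is clamped, and
out-of-range scores are flagged rather than hidden.

With DIF-adjusted parameters each respondent is scored - numerator and
plausible maximum alike - with their own gender's parameters, so both
genders span exactly [0, 81]; a common pooled denominator is available via
``denominator="common"`` (it uses the male/female-averaged maxima).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import ResponseRecord, frequency_sum_score, unweighted_sum_score
from .params import GrmItemParams, NrmItemParams

__all__ = [
    "WeightedScore",
    "grm_item_weight",
    "nrm_category_weight",
    "score_grm",
    "score_nrm",
    "score_cohort",
]

SCALE_MAX = 81.0


@dataclass(frozen=True)
class WeightedScore:
    raw: float
    normalized: float
    rescaled: float
    method: str


def grm_item_weight(a: float, b_k: float) -> float:
    """Weight of an endorsed GRM category: discrimination times threshold."""
    return float(a) * float(b_k)


def nrm_category_weight(item: NrmItemParams, label: int) -> float:
    """Weight of an endorsed NRM combination category: slope plus intercept."""
    if label == 0:
        return 0.0
    a, c = item.value(label)
    return a + c


def _resolve_threshold(item: GrmItemParams, k: int) -> float:
    """Threshold for category k >= 1, filling NaN from the nearest neighbour.

    A NaN threshold means the category was never observed when the parameters
    were estimated; the next higher (preferred, since P(X >= k) is then equal
    for the two categories) or next lower estimated threshold stands in.
    """
    b = item.b
    if np.isfinite(b[k - 1]):
        return float(b[k - 1])
    for j in range(k, len(b)):  # next higher
        if np.isfinite(b[j]):
            return float(b[j])
    for j in range(k - 2, -1, -1):  # next lower
        if np.isfinite(b[j]):
            return float(b[j])
    raise ValueError("item has no estimated thresholds")


def _item_sets(params, model: str) -> dict[str, Sequence]:
    """Normalise the accepted parameter shapes to {group: [9 item params]}."""
    from .dif import DifAdjustedParams  # local import to avoid a cycle

    if isinstance(params, DifAdjustedParams):
        if params.model != model:
            raise ValueError(f"expected {model} parameters, got {params.model}")
        return params.params
    if isinstance(params, Mapping):
        return dict(params)
    return {"all": list(params)}


def _select_group(sets: dict[str, Sequence], rec: ResponseRecord) -> Sequence:
    if "all" in sets and len(sets) == 1:
        return sets["all"]
    if rec.gender is None:
        raise ValueError(
            f"record {rec.respondent_id!r} has no gender but the parameter set "
            "is gender-specific"
        )
    return sets[rec.gender]


def _grm_max(items: Sequence[GrmItemParams]) -> float:
    return sum(grm_item_weight(p.a, _resolve_threshold(p, len(p.b))) for p in items)


def _nrm_max(items: Sequence[NrmItemParams]) -> float:
    total = 0.0
    for p in items:
        weights = [0.0] + [
            p.a[i] + p.c[i]
            for i, lab in enumerate(p.labels)
            if lab != 0 and np.isfinite(p.a[i]) and np.isfinite(p.c[i])
        ]
        total += max(weights)
    return total


def score_grm(
    rec: ResponseRecord,
    params,
    method: str = "grm",
    denominator: Literal["per-gender", "common"] = "per-gender",
) -> WeightedScore:
    """GRM weighted sum score for one respondent, rescaled to 0-81."""
    sets = _item_sets(params, "grm")
    items = _select_group(sets, rec)
    cats = rec.product_categories()
    raw = sum(
        grm_item_weight(p.a, _resolve_threshold(p, k)) if k > 0 else 0.0
        for p, k in zip(items, cats)
    )
    if denominator == "common":
        denom = float(np.mean([_grm_max(s) for s in sets.values()]))
    else:
        denom = _grm_max(items)
    if denom <= 0:
        raise ValueError("plausible maximum weighted score is not positive")
    normalized = raw / denom
    return WeightedScore(raw, normalized, normalized * SCALE_MAX, method)


def score_nrm(
    rec: ResponseRecord,
    params,
    method: str = "nrm",
    denominator: Literal["per-gender", "common"] = "per-gender",
) -> WeightedScore:
    """NRM weighted sum score for one respondent, rescaled to 0-81.

    Substituted cells (filled by the sparse-cell rule) are used
    transparently; a response in a cell with no value at all is an error.
    """
    sets = _item_sets(params, "nrm")
    items = _select_group(sets, rec)
    raw = 0.0
    for i, (p, label) in enumerate(zip(items, rec.combination_categories()), start=1):
        if label == 0:
            continue
        idx = p.labels.index(label)
        if not (np.isfinite(p.a[idx]) and np.isfinite(p.c[idx])):
            raise ValueError(
                f"item {i}: category {label} has no parameter value (cell never "
                "estimated and not substituted)"
            )
        raw += p.a[idx] + p.c[idx]
    if denominator == "common":
        denom = float(np.mean([_nrm_max(s) for s in sets.values()]))
    else:
        denom = _nrm_max(items)
    if denom <= 0:
        raise ValueError("plausible maximum weighted score is not positive")
    normalized = raw / denom
    return WeightedScore(raw, normalized, normalized * SCALE_MAX, method)


def score_cohort(
    records: Sequence[ResponseRecord],
    params=None,
    method: str = "unweighted",
    denominator: Literal["per-gender", "common"] = "per-gender",
) -> pd.DataFrame:
    """Score every complete record with one method; one row per respondent.

    ``method`` is ``unweighted``/``frequency`` (no parameters needed), or a
    label starting with ``grm``/``nrm`` (e.g. ``grm_dif``) with a matching
    parameter set. Out-of-[0, 81] rescaled values are flagged, not clamped.
    """
    rows = []
    for rec in records:
        if not rec.complete:
            continue
        if method == "unweighted":
            raw = float(unweighted_sum_score(rec))
            score = WeightedScore(raw, raw / SCALE_MAX, raw, method)
        elif method == "frequency":
            raw = float(frequency_sum_score(rec))
            score = WeightedScore(raw, raw / 27.0, raw, method)
        elif method.startswith("grm"):
            score = score_grm(rec, params, method, denominator)
        elif method.startswith("nrm"):
            score = score_nrm(rec, params, method, denominator)
        else:
            raise ValueError(f"unknown scoring method {method!r}")
        rows.append(
            {
                "id": rec.respondent_id,
                "method": method,
                "raw": score.raw,
                "normalized": score.normalized,
                "rescaled": score.rescaled,
                "gender": rec.gender,
                "severity_group": rec.severity_group,
                "out_of_range": not (0.0 <= score.rescaled <= SCALE_MAX + 1e-9),
            }
        )
    return pd.DataFrame(rows)
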