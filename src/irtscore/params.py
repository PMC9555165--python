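"""Item-parameter containers and their delimited-table serialisation.

GRM items carry one discrimination and six ordered thresholds (seven ordinal
product categories); NRM items carry a category slope and intercept for each
of the ten nominal combination categories, with the no-symptom category 0
fixed at slope = intercept = 0 for identification. NRM cells that could not
be estimated for a gender (no endorsements) may be filled by the substitution
rule in :mod:`irtscore.dif`; such cells carry a provenance tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instrument import COMBINATION_LABELS, ITEM_NAMES

__all__ = [
    "GrmItemParams",
    "NrmItemParams",
    "grm_params_to_frame",
    "grm_params_from_frame",
    "nrm_params_to_frame",
    "nrm_params_from_frame",
    "write_params",
    "read_params",
]

#: Provenance tags for substituted NRM cells.
SOURCE_OTHER_GENDER = "other-gender"
SOURCE_PREVIOUS_FREQUENCY = "previous-frequency"


@dataclass
class GrmItemParams:
    """One GRM item: discrimination ``a`` and thresholds ``b[0..K-2]``.

    Thresholds must be strictly increasing among estimated entries; entries
    for categories never observed in a fit are NaN.
    """

    a: float
    b: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        finite = self.b[np.isfinite(self.b)]
        if finite.size >= 2 and np.any(np.diff(finite) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {self.b}")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass
class NrmItemParams:
    """One NRM item over the ten combination categories.

    ``a``/``c`` are length-10 arrays aligned with
    :data:`irtscore.instrument.COMBINATION_LABELS`; index 0 is the reference
    category and is exactly 0. ``substituted`` maps a combination label to the
    provenance tag of its imputed value.
    """

    a: np.ndarray
    c: np.ndarray
    labels: tuple[int, ...] = COMBINATION_LABELS
    substituted: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != (len(self.labels),) or self.c.shape != (len(self.labels),):
            raise ValueError("a and c must have one entry per combination category")
        ref_fixed = self.a[0] == 0.0 and self.c[0] == 0.0
        ref_absent = np.isnan(self.a[0]) and np.isnan(self.c[0])
        if not (ref_fixed or ref_absent):
            raise ValueError(
                "reference category 0 must have a = c = 0 (or NaN when it was "
                "never observed, in which case another category is the pin)"
            )

    def value(self, label: int) -> tuple[float, float]:
        idx = self.labels.index(label)
        return float(self.a[idx]), float(self.c[idx])


# ---------------------------------------------------------------------------
# Table round-trips (6-decimal fidelity)
# ---------------------------------------------------------------------------


def grm_params_to_frame(items: Mapping[str, Sequence[GrmItemParams]]) -> pd.DataFrame:
    """``{group: [9 GrmItemParams]}`` to a table with columns item, group, a, b1..b6."""
    rows = []
    for group, params in items.items():
        for i, p in enumerate(params, start=1):
            row = {"item": i, "name": ITEM_NAMES[i - 1], "group": group,
                   "a": round(float(p.a), 6)}
            for k, bk in enumerate(p.b, start=1):
                row[f"b{k}"] = round(float(bk), 6) if np.isfinite(bk) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def grm_params_from_frame(frame: pd.DataFrame) -> dict[str, list[GrmItemParams]]:
    b_cols = sorted((c for c in frame.columns if c.startswith("b")), key=lambda c: int(c[1:]))
    out: dict[str, list[GrmItemParams]] = {}
    for group, sub in frame.groupby("group", sort=False):
        sub = sub.sort_values("item")
        out[str(group)] = [
            GrmItemParams(a=float(r["a"]), b=np.array([r[c] for c in b_cols], dtype=float))
            for _, r in sub.iterrows()
        ]
    return out


def nrm_params_to_frame(items: Mapping[str, Sequence[NrmItemParams]]) -> pd.DataFrame:
    """Long table: item, group, category, a, c, substituted (provenance tag or '')."""
    rows = []
    for group, params in items.items():
        for i, p in enumerate(params, start=1):
            for idx, label in enumerate(p.labels):
                if label == 0:
                    continue  # fixed reference category
                rows.append({
                    "item": i,
                    "name": ITEM_NAMES[i - 1],
                    "group": group,
                    "category": label,
                    "a": round(float(p.a[idx]), 6) if np.isfinite(p.a[idx]) else np.nan,
                    "c": round(float(p.c[idx]), 6) if np.isfinite(p.c[idx]) else np.nan,
                    "substituted": p.substituted.get(label, ""),
                })
    return pd.DataFrame(rows)


def nrm_params_from_frame(frame: pd.DataFrame) -> dict[str, list[NrmItemParams]]:
    out: dict[str, list[NrmItemParams]] = {}
    for group, sub in frame.groupby("group", sort=False):
        params: list[NrmItemParams] = []
        for item in sorted(sub["item"].unique()):
            block = sub[sub["item"] == item].set_index("category")
            a = np.zeros(len(COMBINATION_LABELS))
            c = np.zeros(len(COMBINATION_LABELS))
            subst: dict[int, str] = {}
            for idx, label in enumerate(COMBINATION_LABELS):
                if label == 0:
                    continue
                row = block.loc[label]
                a[idx] = float(row["a"])
                c[idx] = float(row["c"])
                tag = row.get("substituted", "")
                if isinstance(tag, str) and tag:
                    subst[label] = tag
            params.append(NrmItemParams(a=a, c=c, substituted=subst))
        out[str(group)] = params
    return out


def write_params(items: Mapping[str, Sequence[object]], path: str | Path) -> None:
    path = Path(path)
    first = next(iter(items.values()))[0]
    if isinstance(first, GrmItemParams):
        frame = grm_params_to_frame(items)  # type: ignore[arg-type]
    elif isinstance(first, NrmItemParams):
        frame = nrm_params_to_frame(items)  # type: ignore[arg-type]
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown parameter type {type(first)}")
    frame.to_csv(path, index=False)


def read_params(path: str | Path, model: str) -> dict[str, list]:
    frame = pd.read_csv(path, keep_default_na=True)
    if "substituted" in frame.columns:
        frame["substituted"] = frame["substituted"].fillna("")
    if model == "grm":
        return grm_params_from_frame(frame)
    if model == "nrm":
        return nrm_params_from_frame(frame)
    raise ValueError(f"unknown model {model!r}")
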