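"""The 9Q instrument: response coding, category maps, and classical sum scores.

The Nine-Questions Depression-Rating Scale (9Q) asks, for each of nine
depressive symptoms, how intense the symptom was over the previous two weeks
(0 = no symptoms, 1 = mild, 2 = moderate, 3 = severe) and, when present, how
frequent (1 = several days, 2 = more than a week, 3 = nearly every day).
Each item is traditionally scored as the product intensity x frequency, which
can take the seven values {0, 1, 2, 3, 4, 6, 9}; the nine products sum to the
0-81 total score.

Two codings of an item response are used downstream:

* the *product category*, an ordinal label 0-6 mapping one-to-one onto the
  seven product values (used by the graded-response model), and
* the *combination category*, a nominal label in {0, 11, 12, 13, 21, 22, 23,
  31, 32, 33} whose tens digit is the intensity and units digit the frequency
  (used by the nominal-response model, which does not assume an ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_NAMES",
    "N_ITEMS",
    "PRODUCT_POINTS",
    "PRODUCT_CATEGORIES",
    "COMBINATION_LABELS",
    "CodingError",
    "IncompleteRecordError",
    "ItemResponse",
    "ResponseRecord",
    "product_score",
    "product_category",
    "combination_category",
    "unweighted_sum_score",
    "frequency_sum_score",
    "valid_pairs",
    "read_responses",
    "write_responses",
    "records_to_frame",
    "category_matrix",
]

#: 1-based item order used in every report.
ITEM_NAMES = (
    "Mood",
    "Interest",
    "Sleep",
    "Fatigue",
    "Weight",
    "Guilty",
    "Concentration",
    "Psychomotor",
    "Suicide",
)
N_ITEMS = 9

#: Traditional product points, index = ordinal product category 0..6.
PRODUCT_POINTS = (0, 1, 2, 3, 4, 6, 9)
PRODUCT_CATEGORIES = tuple(range(7))
_POINT_TO_CATEGORY = {p: k for k, p in enumerate(PRODUCT_POINTS)}

#: Nominal combination labels; tens digit = intensity, units digit = frequency.
COMBINATION_LABELS = (0, 11, 12, 13, 21, 22, 23, 31, 32, 33)
COMBINATION_INDEX = {lab: i for i, lab in enumerate(COMBINATION_LABELS)}

GENDERS = ("male", "female")
SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")
COHORTS = ("developmental", "validation")


class CodingError(ValueError):
    """An (intensity, frequency) pair outside the instrument's code book."""


class IncompleteRecordError(ValueError):
    """Raised when an operation requiring all nine items gets a partial record."""


@dataclass(frozen=True)
class ItemResponse:
    """A single item's (intensity, frequency) pair.

    Frequency 0 is only valid together with intensity 0 (no symptom, hence no
    frequency); a symptomatic response must carry a frequency of 1-3.
    """

    intensity: int
    frequency: int

    def __post_init__(self) -> None:
        i, f = self.intensity, self.frequency
        if i not in (0, 1, 2, 3) or f not in (0, 1, 2, 3):
            raise CodingError(f"intensity/frequency codes out of range: ({i}, {f})")
        if (i == 0) != (f == 0):
            raise CodingError(
                f"intensity {i} with frequency {f}: frequency 0 is valid only "
                "for intensity 0 (and vice versa)"
            )


def valid_pairs() -> tuple[ItemResponse, ...]:
    """All 10 valid (intensity, frequency) pairs of the instrument."""
    pairs = [ItemResponse(0, 0)]
    pairs += [ItemResponse(i, f) for i in (1, 2, 3) for f in (1, 2, 3)]
    return tuple(pairs)


def product_score(r: ItemResponse, item: int | None = None) -> int:
    """Traditional item score: intensity x frequency, in {0,1,2,3,4,6,9}."""
    try:
        score = r.intensity * r.frequency
    except (TypeError, AttributeError) as exc:  # pragma: no cover - defensive
        raise CodingError(f"invalid response for item {item}: {r!r}") from exc
    return score


def product_category(r: ItemResponse) -> int:
    """Ordinal product category 0-6 (bijective with the product points).

    Pairs with equal products share a category: (1, 3) and (3, 1) both score
    3 points and both map to category 3.
    """
    return _POINT_TO_CATEGORY[product_score(r)]


def category_to_point(category: int) -> int:
    """Inverse of the ordinal coding: category 0-6 back to {0,1,2,3,4,6,9}."""
    return PRODUCT_POINTS[category]


def combination_category(r: ItemResponse) -> int:
    """Nominal combination label: intensity*10 + frequency, or 0 for none."""
    if r.intensity == 0:
        return 0
    return r.intensity * 10 + r.frequency


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent: nine item responses plus covariates.

    ``responses`` holds ``None`` for unanswered items; such records are
    *incomplete* and are excluded from estimation, matching the handling of
    non-completers in the instrument's validation studies.
    """

    responses: tuple[ItemResponse | None, ...]
    gender: str | None = None
    severity_group: str | None = None
    cohort: str | None = None
    respondent_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.responses) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item slots, got {len(self.responses)}")
        if self.gender is not None and self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.severity_group is not None and self.severity_group not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity group {self.severity_group!r}")
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")

    @property
    def complete(self) -> bool:
        return all(r is not None for r in self.responses)

    def _require_complete(self) -> None:
        if not self.complete:
            missing = [i + 1 for i, r in enumerate(self.responses) if r is None]
            raise IncompleteRecordError(
                f"record {self.respondent_id!r} is incomplete (items {missing}); "
                "incomplete records are excluded"
            )

    def product_categories(self) -> tuple[int, ...]:
        self._require_complete()
        return tuple(product_category(r) for r in self.responses)

    def combination_categories(self) -> tuple[int, ...]:
        self._require_complete()
        return tuple(combination_category(r) for r in self.responses)


def unweighted_sum_score(rec: ResponseRecord) -> int:
    """Classical 9Q total: sum of the nine intensity x frequency products (0-81)."""
    rec._require_complete()
    return sum(product_score(r, item=i + 1) for i, r in enumerate(rec.responses))


def frequency_sum_score(rec: ResponseRecord) -> int:
    """Sum of the nine frequency codes (0-27); the frequency-only comparator."""
    rec._require_complete()
    return sum(r.frequency for r in rec.responses)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["id", "gender", "severity_group", "cohort"] + [
    f"i{i}_{part}" for i in range(1, N_ITEMS + 1) for part in ("int", "freq")
]


def records_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Flatten records into the canonical wide table (one row per respondent)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "id": rec.respondent_id,
            "gender": rec.gender,
            "severity_group": rec.severity_group,
            "cohort": rec.cohort,
        }
        for i, r in enumerate(rec.responses, start=1):
            row[f"i{i}_int"] = None if r is None else r.intensity
            row[f"i{i}_freq"] = None if r is None else r.frequency
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    item_cols = _COLUMNS[4:]
    frame[item_cols] = frame[item_cols].astype("Int64")  # no trailing .0 on disk
    return frame


def write_responses(records: Sequence[ResponseRecord], path: str | Path) -> None:
    """Write records as CSV (or TSV if the suffix is .tsv)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def _parse_gender(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    text = str(value).strip().lower()
    if text in ("m", "male"):
        return "male"
    if text in ("f", "female"):
        return "female"
    raise ValueError(f"unknown gender code {value!r}")


def _parse_code(value: object) -> int | None:
    if value is None or value == "":
        return None
    number = float(value)
    if np.isnan(number):
        return None
    if not number.is_integer():
        raise ValueError(f"non-integer response code {value!r}")
    return int(number)


def read_responses(
    path: str | Path,
    fmt: Literal["csv", "tsv", None] = None,
    on_invalid: Literal["raise", "skip"] = "raise",
) -> list[ResponseRecord]:
    """Read respondent records from a delimited table.

    Expects columns ``id, gender, severity_group, cohort, i1_int, i1_freq, ...,
    i9_int, i9_freq``. Gender accepts ``m/f`` case-insensitively; a blank
    frequency with intensity 0 is normalised to frequency 0; a blank intensity
    marks the item as unanswered (the record is kept but flagged incomplete).
    Invalid rows are reported with their row index and reason; with
    ``on_invalid="skip"`` they are dropped with a warning instead of raising.
    Duplicate respondent ids are always a hard error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() == ".tsv" else "csv"
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=object)
    missing_cols = [c for c in _COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")

    ids = frame["id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate respondent ids {list(dup)[:5]}")

    records: list[ResponseRecord] = []
    problems: list[str] = []
    for idx, row in frame.iterrows():
        try:
            responses: list[ItemResponse | None] = []
            for i in range(1, N_ITEMS + 1):
                intensity = _parse_code(row[f"i{i}_int"])
                freq = _parse_code(row[f"i{i}_freq"])
                if intensity is None:
                    responses.append(None)
                    continue
                if freq is None:
                    if intensity == 0:
                        freq = 0  # blank frequency is legal shorthand for "no symptom"
                    else:
                        raise CodingError(
                            f"item {i}: intensity {intensity} with blank frequency"
                        )
                responses.append(ItemResponse(intensity, freq))
            sev = row["severity_group"]
            sev = None if pd.isna(sev) or sev == "" else str(sev).strip().lower()
            coh = row["cohort"]
            coh = None if pd.isna(coh) or coh == "" else str(coh).strip().lower()
            records.append(
                ResponseRecord(
                    responses=tuple(responses),
                    gender=_parse_gender(row["gender"]),
                    severity_group=sev,
                    cohort=coh,
                    respondent_id=str(row["id"]),
                )
            )
        except (CodingError, ValueError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        message = f"{path}: {len(problems)} invalid rows:\n  " + "\n  ".join(problems)
        if on_invalid == "raise":
            raise ValueError(message)
        warnings.warn(message, stacklevel=2)
    return records


def category_matrix(
    records: Sequence[ResponseRecord],
    coding: Literal["product", "combination"] = "product",
) -> np.ndarray:
    """Complete records as an (N, 9) integer matrix of category *indices*.

    Product coding yields ordinal categories 0-6; combination coding yields
    indices 0-9 into :data:`COMBINATION_LABELS`. Incomplete records are
    silently excluded (they never enter estimation).
    """
    rows = []
    for rec in records:
        if not rec.complete:
            continue
        if coding == "product":
            rows.append(rec.product_categories())
        elif coding == "combination":
            rows.append([COMBINATION_INDEX[c] for c in rec.combination_categories()])
        else:
            raise ValueError(f"unknown coding {coding!r}")
    return np.asarray(rows, dtype=np.int64).reshape(len(rows), N_ITEMS)
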