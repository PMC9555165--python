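"""Synthetic study-like cohorts with known ground truth.

The real calibration data cannot be shared, so every stage of the workflow is
exercised on simulated cohorts drawn from the published parameter values: a
latent severity theta ~ N(0,1) per respondent, gender drawn with the study's
female fraction (about 0.68), item categories drawn from the GRM or NRM
category probabilities at that respondent's theta (with optional
gender-specific threshold shifts to inject uniform DIF), and severity-group
labels cut from fixed theta quantiles chosen to mimic the validation cohort's
none/mild/moderate/severe composition of 302/31/14/8 out of 355.

The generator emits ordinary :class:`~irtscore.instrument.ResponseRecord`
objects (and schema-valid CSV via ``write_responses``), so simulated cohorts
flow through ingestion, estimation, scoring and evaluation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .instrument import N_ITEMS, ItemResponse, ResponseRecord
from .models import grm_prob_table, nrm_prob_table
from .params import GrmItemParams
from .reference import load_reference_grm, load_reference_nrm

__all__ = [
    "SimulationConfig",
    "simulate_grm_cohort",
    "simulate_nrm_cohort",
    "split_cohort",
    "back_map_product_to_pair",
    "default_severity_cuts",
]

#: Canonical (intensity, frequency) representative for each product category.
#: Products 3 and 6 are ambiguous ((1,3)/(3,1) and (2,3)/(3,2)); one
#: representative is fixed so the ordinal round-trip is exact. The NRM
#: simulator, which distinguishes the pairs, exercises combination-level
#: behaviour.
_PRODUCT_BACKMAP = {
    0: (0, 0),
    1: (1, 1),
    2: (2, 1),
    3: (3, 1),
    4: (2, 2),
    5: (2, 3),
    6: (3, 3),
}

#: Validation-cohort severity composition used for the default theta cuts.
_SEVERITY_COUNTS = (302, 31, 14, 8)


def default_severity_cuts() -> tuple[float, float, float]:
    """Theta cuts reproducing the 302/31/14/8 group proportions in expectation."""
    total = sum(_SEVERITY_COUNTS)
    cum = np.cumsum(_SEVERITY_COUNTS)[:-1] / total
    return tuple(float(stats.norm.ppf(p)) for p in cum)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-emulating generator settings.

    Defaults are the study conditions: cohort size 1,355, female fraction
    0.679, standard-normal severity, the published parameter values as
    generating truth, and severity cuts from the validation-group
    composition. ``dif_shifts`` maps a 1-based item to a threshold shift
    added to the female thresholds (GRM; a mapping ``{"male": s, "female": s}``
    is also accepted). ``absent_cells`` lists (item, gender, label)
    combination cells forced unobserved (drawn responses fall back to the
    previous frequency at the same intensity), used to exercise the
    sparse-cell substitution rule.
    """

    n: int = 1355
    female_fraction: float = 0.679
    seed: int = 0
    params: Mapping[str, Sequence] | None = None
    dif_shifts: Mapping[int, object] = field(default_factory=dict)
    absent_cells: tuple[tuple[int, str, int], ...] = ()
    severity_cuts: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        cuts = self.severity_cuts
        if cuts is not None and np.any(np.diff(cuts) <= 0):
            raise ValueError("severity cuts must be strictly increasing")


def _severity_label(theta: float, cuts: Sequence[float]) -> str:
    labels = ("none", "mild", "moderate", "severe")
    return labels[int(np.searchsorted(cuts, theta, side="right"))]


def _genders(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    return np.where(
        rng.random(config.n) < config.female_fraction, "female", "male"
    )


def _shifted(item: GrmItemParams, shift: object, gender: str) -> GrmItemParams:
    if isinstance(shift, Mapping):
        delta = float(shift.get(gender, 0.0))
    else:
        delta = float(shift) if gender == "female" else 0.0
    if delta == 0.0:
        return item
    return GrmItemParams(a=item.a, b=item.b + delta)


def simulate_grm_cohort(config: SimulationConfig) -> list[ResponseRecord]:
    """Draw a cohort from GRM category probabilities (product coding).

    Ordinal product categories are drawn per item and back-mapped to their
    canonical (intensity, frequency) pair, so the records are schema-valid
    instrument responses.
    """
    rng = np.random.default_rng(config.seed)
    base = dict(config.params) if config.params is not None else load_reference_grm("pooled")
    if "all" in base:
        base = {"male": base["all"], "female": base["all"]}
    cuts = config.severity_cuts or default_severity_cuts()
    theta = rng.standard_normal(config.n)
    genders = _genders(rng, config)

    u = rng.random((config.n, N_ITEMS))
    cats = np.zeros((config.n, N_ITEMS), dtype=np.int64)
    for gender in ("male", "female"):
        rows = np.flatnonzero(genders == gender)
        if rows.size == 0:
            continue
        for i, p in enumerate(base[gender], start=1):
            p = _shifted(p, config.dif_shifts.get(i, 0.0), gender)
            table = grm_prob_table(p.a, p.b[np.isfinite(p.b)], theta[rows])  # (K, n_g)
            cum = np.cumsum(table, axis=0)
            k = (u[rows, i - 1][None, :] > cum).sum(axis=0)
            cats[rows, i - 1] = np.minimum(k, table.shape[0] - 1)

    records = []
    for j in range(config.n):
        responses = tuple(back_map_product_to_pair(c) for c in cats[j])
        records.append(
            ResponseRecord(
                responses=responses,
                gender=str(genders[j]),
                severity_group=_severity_label(theta[j], cuts),
                respondent_id=f"sim{j:05d}",
            )
        )
    return records


def _previous_frequency_label(label: int) -> int:
    intensity, freq = divmod(label, 10)
    if freq > 1:
        return intensity * 10 + (freq - 1)
    return 0


def simulate_nrm_cohort(config: SimulationConfig) -> list[ResponseRecord]:
    """Draw a cohort from NRM softmax probabilities over the 10 combinations.

    Cells named in ``absent_cells`` are never emitted: a draw landing there is
    demoted to the previous frequency at the same intensity, which produces
    the structurally missing cells the substitution rule exists for.
    """
    rng = np.random.default_rng(config.seed)
    base = dict(config.params) if config.params is not None else load_reference_nrm("pooled")
    if "all" in base:
        base = {"male": base["all"], "female": base["all"]}
    cuts = config.severity_cuts or default_severity_cuts()
    theta = rng.standard_normal(config.n)
    genders = _genders(rng, config)
    absent = set(config.absent_cells)

    u = rng.random((config.n, N_ITEMS))
    drawn = np.zeros((config.n, N_ITEMS), dtype=np.int64)  # combination labels
    for gender in ("male", "female"):
        rows = np.flatnonzero(genders == gender)
        if rows.size == 0:
            continue
        for i, p in enumerate(base[gender], start=1):
            finite = np.isfinite(p.a) & np.isfinite(p.c)
            labels = np.array([lab for lab, ok in zip(p.labels, finite) if ok])
            table = nrm_prob_table(p.a[finite], p.c[finite], theta[rows])
            cum = np.cumsum(table, axis=0)
            k = (u[rows, i - 1][None, :] > cum).sum(axis=0)
            lab = labels[np.minimum(k, len(labels) - 1)]
            if absent:
                for jj in range(lab.size):
                    label = int(lab[jj])
                    while (i, gender, label) in absent and label != 0:
                        label = _previous_frequency_label(label)
                    lab[jj] = label
            drawn[rows, i - 1] = lab

    records = []
    for j in range(config.n):
        responses = tuple(
            ItemResponse(*divmod(int(label), 10)) for label in drawn[j]
        )
        records.append(
            ResponseRecord(
                responses=responses,
                gender=str(genders[j]),
                severity_group=_severity_label(theta[j], cuts),
                respondent_id=f"sim{j:05d}",
            )
        )
    return records


def split_cohort(
    records: Sequence[ResponseRecord],
    dev_fraction: float = 1000 / 1355,
    seed: int = 0,
) -> tuple[list[ResponseRecord], list[ResponseRecord]]:
    """Gender-stratified random split into developmental / validation cohorts.

    Each gender contributes ``round(dev_fraction * n_gender)`` records to the
    developmental set, so the split's female fraction matches the cohort's to
    within one record. Records are tagged with their cohort.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_gender: dict[object, list[int]] = {}
    for idx, rec in enumerate(records):
        by_gender.setdefault(rec.gender, []).append(idx)
    dev_idx: set[int] = set()
    for gender, idxs in by_gender.items():
        if len(idxs) < 2:
            raise ValueError(f"gender stratum {gender!r} has fewer than 2 records")
        take = int(round(dev_fraction * len(idxs)))
        chosen = rng.choice(len(idxs), size=take, replace=False)
        dev_idx.update(idxs[c] for c in chosen)
    dev, val = [], []
    for idx, rec in enumerate(records):
        if idx in dev_idx:
            dev.append(replace(rec, cohort="developmental"))
        else:
            val.append(replace(rec, cohort="validation"))
    return dev, val


def back_map_product_to_pair(category: int) -> ItemResponse:
    """Canonical (intensity, frequency) pair for an ordinal product category."""
    try:
        intensity, freq = _PRODUCT_BACKMAP[int(category)]
    except KeyError:
        raise ValueError(f"unknown product category {category!r}") from None
    return ItemResponse(intensity, freq)
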