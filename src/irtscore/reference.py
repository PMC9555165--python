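"""Loaders for the published 9Q reference values shipped with the package.

These small tables hold the published calibration of the 9Q instrument on its
adult developmental sample: GRM discriminations/thresholds (pooled and
gender-DIF-adjusted), NRM category slopes/intercepts (with the published
substitution footnotes preserved as provenance flags), the published item-fit
chi-square/p pairs, and the published validation-cohort evaluation table
(group means, F statistics, relative precision). They serve two roles:
realistic default generating values for the synthetic-cohort module, and
fixed inputs for the arithmetic-consistency checks in the test-suite.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .instrument import COMBINATION_LABELS
from .params import GrmItemParams, NrmItemParams

__all__ = [
    "load_reference_grm",
    "load_reference_nrm",
    "load_reference_item_fit",
    "load_reference_evaluation",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("irtscore.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_reference_grm(which: str = "pooled") -> dict[str, list[GrmItemParams]]:
    """Reference GRM parameters.

    ``which="pooled"`` returns ``{"all": [9 items]}``; ``which="dif"`` returns
    ``{"male": [...], "female": [...]}`` where non-DIF items (published for
    both genders jointly) are identical across the two groups and DIF items
    (Interest, Weight) carry gender-specific thresholds with a shared slope.
    """
    frame = _read("grm_reference_params.csv")
    frame = frame[frame["set"] == which]
    if frame.empty:
        raise ValueError(f"unknown parameter set {which!r}")
    b_cols = [f"b{k}" for k in range(1, 7)]

    def _mk(row: pd.Series) -> GrmItemParams:
        return GrmItemParams(a=float(row["a"]), b=row[b_cols].to_numpy(dtype=float))

    if which == "pooled":
        items = [_mk(r) for _, r in frame.sort_values("item").iterrows()]
        return {"all": items}
    out: dict[str, list[GrmItemParams]] = {"male": [], "female": []}
    for item in range(1, 10):
        block = frame[frame["item"] == item]
        for gender in ("male", "female"):
            row = block[block["group"].isin([gender, "all"])].iloc[0]
            out[gender].append(_mk(row))
    return out


def load_reference_nrm(which: str = "pooled") -> dict[str, list[NrmItemParams]]:
    """Reference NRM parameters (``pooled`` -> {"all"}; ``dif`` -> per gender)."""
    frame = _read("nrm_reference_params.csv")
    frame = frame[frame["set"] == which]
    if frame.empty:
        raise ValueError(f"unknown parameter set {which!r}")
    v_cols = [f"v{lab}" for lab in COMBINATION_LABELS if lab != 0]
    f_cols = [f"f{lab}" for lab in COMBINATION_LABELS if lab != 0]

    def _mk(block: pd.DataFrame) -> NrmItemParams:
        a_row = block[block["param"] == "a"].iloc[0]
        c_row = block[block["param"] == "c"].iloc[0]
        a = np.concatenate([[0.0], a_row[v_cols].to_numpy(dtype=float)])
        c = np.concatenate([[0.0], c_row[v_cols].to_numpy(dtype=float)])
        subst = {
            lab: "published"
            for lab, fa, fc in zip(
                [l for l in COMBINATION_LABELS if l != 0],
                a_row[f_cols].to_numpy(dtype=int),
                c_row[f_cols].to_numpy(dtype=int),
            )
            if fa or fc
        }
        return NrmItemParams(a=a, c=c, substituted=subst)

    if which == "pooled":
        return {"all": [_mk(frame[frame["item"] == i]) for i in range(1, 10)]}
    out: dict[str, list[NrmItemParams]] = {"male": [], "female": []}
    for item in range(1, 10):
        block = frame[frame["item"] == item]
        for gender in ("male", "female"):
            sub = block[block["group"].isin([gender, "all"])]
            out[gender].append(_mk(sub))
    return out


def load_reference_item_fit() -> pd.DataFrame:
    """Published per-item chi-square fit statistics with printed p-values.

    ``p_text`` keeps the printed form (e.g. ``"<0.001"``); ``p_upper`` is the
    usable numeric upper bound (0.001 for censored entries, else the value).
    """
    frame = _read("item_fit_reference.csv")
    frame["censored"] = frame["p_text"].str.startswith("<")
    frame["p_upper"] = frame["p_text"].str.lstrip("<").astype(float)
    return frame


def load_reference_evaluation() -> pd.DataFrame:
    """Published validation-cohort evaluation table (long layout).

    Rows are (method, quantity) with group columns ``none..severe`` and
    pairwise columns ``d01..d23``; quantities are mean, se, mean_diff, F and
    RP, plus the severity-group sizes under method ``groups``.
    """
    return _read("evaluation_reference.csv")
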