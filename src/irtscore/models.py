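"""Category-probability functions for the two polytomous IRT models.

GRM (graded-response model): item ``i`` has discrimination ``a_i`` and
strictly increasing thresholds ``b_i1 < ... < b_i,K-1``. With the logistic
cumulative curves ``P(X >= k | theta) = sigma(a_i (theta - b_ik))`` the
category probability is the difference of adjacent curves,

    P_ik(theta) = sigma(a_i (theta - b_ik)) - sigma(a_i (theta - b_i,k+1)),

with the boundary conventions b_i0 = -inf and b_iK = +inf.

NRM (nominal-response model): item ``i`` has a slope/intercept per category
and the probabilities are a softmax,

    P_ik(theta) = exp(a_ik theta + c_ik) / sum_m exp(a_im theta + c_im),

with the reference category fixed at a = c = 0. Categories need no ordering,
which is what lets the NRM score the ten intensity-frequency combinations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, softmax

from .params import GrmItemParams, NrmItemParams

__all__ = [
    "grm_prob_table",
    "grm_category_prob",
    "grm_expected_score",
    "nrm_prob_table",
    "nrm_category_prob",
]


def grm_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(K, Q) matrix of GRM category probabilities at each node.

    ``b`` must contain only finite values here (collapse unobserved
    categories before calling); rows sum to one by the telescoping of the
    cumulative curves.
    """
    b = np.asarray(b, dtype=float)
    if b.size and np.any(np.diff(b) <= 0):
        raise ValueError(f"thresholds must be strictly increasing, got {b}")
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    cum = expit(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
    ext = np.vstack([np.ones_like(nodes), cum, np.zeros_like(nodes)])
    return ext[:-1] - ext[1:]


def grm_category_prob(theta: float, item: GrmItemParams, k: int) -> float:
    """P(category k | theta) for one GRM item."""
    b = item.b[np.isfinite(item.b)]
    table = grm_prob_table(item.a, b, np.array([theta]))
    return float(table[k, 0])


def grm_expected_score(
    item: GrmItemParams, nodes: np.ndarray, scores: np.ndarray | None = None
) -> np.ndarray:
    """E[item score | theta] at each node; default scores are 0..K-1."""
    b = item.b[np.isfinite(item.b)]
    table = grm_prob_table(item.a, b, nodes)
    if scores is None:
        scores = np.arange(table.shape[0], dtype=float)
    return scores @ table


def nrm_prob_table(a: np.ndarray, c: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(K, Q) matrix of NRM (softmax) category probabilities at each node."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(c)):
        raise ValueError("NRM parameters must be finite")
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    logits = a[:, None] * nodes[None, :] + c[:, None]
    return softmax(logits, axis=0)  # max-subtraction inside softmax guards overflow


def nrm_category_prob(theta: float, item: NrmItemParams, label: int) -> float:
    """P(combination category ``label`` | theta) for one NRM item."""
    idx = item.labels.index(label)
    table = nrm_prob_table(item.a, item.c, np.array([theta]))
    return float(table[idx, 0])
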