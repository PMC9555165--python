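"""Quadrature over the latent trait for marginal likelihoods and EAP scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QuadratureGrid", "normal_grid"]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed nodes/weights approximating integrals against the latent prior.

    Weights are strictly positive and sum to one, so sums against them are
    expectations under the (discretised) standard-normal severity prior.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least 2 nodes")
        if weights.shape != nodes.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive and match nodes")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)

    def __len__(self) -> int:
        return len(self.nodes)


def normal_grid(n: int = 61, bound: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-bound, bound] with N(0,1) density weights."""
    nodes = np.linspace(-bound, bound, n)
    return QuadratureGrid(nodes=nodes, weights=stats.norm.pdf(nodes))
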