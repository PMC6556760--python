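"""Patient-to-arm assignment: fixed-ratio and response-adaptive weights.

Response-adaptive randomization (RAR) weights each active arm by the square
root of its posterior probability of being best, renormalized.  A small
floor on the probabilities keeps an unlucky arm from being starved forever.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .posteriors import SuperiorityVector

#: Floor applied to each superiority probability before the sqrt transform.
DEFAULT_FLOOR = 0.01


@dataclass(frozen=True)
class AllocationWeights:
    """Normalized per-arm allocation probabilities."""

    weights: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D sequence")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        w = w / total  # exact normalization
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def __len__(self) -> int:
        return len(self.weights)


def equal_weights(n_arms: int) -> AllocationWeights:
    """1:1:...:1 allocation over ``n_arms`` arms."""
    if n_arms < 2:
        raise ValueError(f"n_arms must be >= 2, got {n_arms}")
    return AllocationWeights((1.0 / n_arms,) * n_arms)


def rar_weights(
    superiority: Union[SuperiorityVector, Sequence[float]],
    floor: float = DEFAULT_FLOOR,
) -> AllocationWeights:
    """Square-root-ratio RAR weights: w_k = sqrt(prob_k) / sum_j sqrt(prob_j).

    The probabilities are normalized first (so the transform is scale-free),
    then floored at ``floor`` so no arm's allocation collapses to zero.
    """
    probs = superiority.probs if isinstance(superiority, SuperiorityVector) else superiority
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("superiority probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("superiority probabilities must not all be zero")
    p = np.maximum(p / total, floor)
    w = np.sqrt(p)
    return AllocationWeights(tuple(w / w.sum()))


def assign_patient(weights: AllocationWeights, rng: np.random.Generator) -> int:
    """Sample an arm index according to the allocation weights."""
    return int(rng.choice(len(weights), p=np.asarray(weights.weights)))
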