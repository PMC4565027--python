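"""Permutation-based empirical p-values and FDR control.

The empirical null is built by shuffling the per-sample gene-score vector
over gene labels and recomputing the set statistic.  This detaches score
magnitude from set membership, which is what corrects count-driven biases
(e.g. long genes accumulating more locus hits by chance).  P-values use the
add-one estimator ``(1 + #extreme) / (n_perm + 1)`` so they are valid and
strictly positive; with ``exhaustive=True`` all label permutations are
enumerated and the estimator becomes the exact fraction (the identity
permutation is part of the enumeration, so no pseudo-count is needed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("two_sided", "greater", "less")

# statistic(scores, member_idx) -> float, deterministic in its inputs
SetStatistic = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class PermutationPlan:
    n_perm: int = 1000
    seed: int = 0
    alternative: str = "two_sided"
    scope: str = "per_sample"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(
                f"alternative must be one of {ALTERNATIVES}, got {self.alternative!r}"
            )
        if self.scope != "per_sample":
            raise ValueError("only per_sample permutation scope is supported")


def _is_extreme(null: np.ndarray, observed: float, alternative: str) -> np.ndarray:
    if alternative == "two_sided":
        return np.abs(null) >= abs(observed) - 1e-12
    if alternative == "greater":
        return null >= observed - 1e-12
    return null <= observed + 1e-12


def empirical_p(
    observed: float,
    statistic: SetStatistic,
    scores: Sequence[float],
    members: Sequence[int],
    plan: PermutationPlan,
    exhaustive: bool = False,
) -> Tuple[float, List[float]]:
    """Permutation p-value for one set statistic within one sample.

    ``scores`` is the per-sample gene-score vector, ``members`` the integer
    positions of the set's genes in it.  Each permutation shuffles the whole
    vector over gene labels and re-applies ``statistic``; set size is fixed.
    """
    x = np.asarray(scores, dtype=float)
    member_idx = np.asarray(members, dtype=int)
    if member_idx.size == 0 or member_idx.size >= x.size:
        raise ValueError("set must be a proper non-empty subset of the universe")
    rng = np.random.default_rng(plan.seed)
    null: List[float] = []
    if exhaustive:
        n = x.size
        if math.factorial(n) > 500_000:
            raise ValueError(f"exhaustive enumeration infeasible for N={n}")
        for perm in itertools.permutations(range(n)):
            null.append(float(statistic(x[np.asarray(perm)], member_idx)))
        null_arr = np.asarray(null)
        p = float(np.mean(_is_extreme(null_arr, observed, plan.alternative)))
    else:
        for _ in range(plan.n_perm):
            null.append(float(statistic(x[rng.permutation(x.size)], member_idx)))
        null_arr = np.asarray(null)
        n_extreme = int(np.sum(_is_extreme(null_arr, observed, plan.alternative)))
        p = (1 + n_extreme) / (plan.n_perm + 1)
    return p, null


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        return p_arr
    if np.any(~np.isfinite(p_arr)) or np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p_arr, method="fdr_bh")
    return q
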