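"""Error metrics and the intervention-aware best-possible-reach (BPR) metric.

An agency with budget to intervene in K of S tracts takes a model's K
highest-predicted tracts as its intervention set I.  BPR scores that set by

    BPR(y, I) = sum_{i in I} y_i / sum_{i in TopKInds(y)} y_i,

the fraction of reachable events actually reached, where TopKInds(y) is the
perfect-hindsight choice of the K largest observed counts.  BPR lies in
[0, 1]; %BPR = 100 * BPR.  An alternative in the literature divides by the
total events over all S tracts instead; its maximum then drifts with the
observed data, which is why the top-K denominator is preferred here.

All functions are pure; randomness enters only through the caller-supplied
generator used for tie-breaking and random-selection averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "InterventionSet",
    "rmse",
    "mae",
    "top_k_indices",
    "top_k_sum",
    "bpr",
    "reach_fraction_all",
    "expected_random_bpr",
    "RandomBPR",
]


@dataclass(frozen=True)
class InterventionSet:
    """K distinct tract indices a model recommends for intervention."""

    indices: tuple[int, ...]
    k: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("intervention set indices must be distinct")
        if len(self.indices) != self.k:
            raise ValueError(f"expected {self.k} indices, got {len(self.indices)}")


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.ndim != 1 or yp.ndim != 1 or len(yt) != len(yp):
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if len(yt) == 0:
        raise ValueError("empty vectors")
    return yt, yp


def rmse(y_true, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error mean(|y - yhat|)."""
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(yt - yp)))


def top_k_indices(
    values,
    k: int,
    rng: np.random.Generator | None = None,
    provenance: str = "",
) -> InterventionSet:
    """Indices of the k largest values, breaking boundary ties at random.

    Every returned index has value >= every excluded index's value; among
    the indices tied exactly at the inclusion boundary the selection is
    uniform at random via ``rng`` (defaults to a fresh generator).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    if not (0 <= k <= len(v)):
        raise ValueError(f"k={k} outside [0, {len(v)}]")
    if k == 0:
        return InterventionSet(indices=(), k=0, provenance=provenance)
    if rng is None:
        rng = np.random.default_rng()
    kth = np.partition(v, len(v) - k)[len(v) - k]
    above = np.flatnonzero(v > kth)
    tied = np.flatnonzero(v == kth)
    need = k - len(above)
    chosen = rng.choice(tied, size=need, replace=False) if need < len(tied) else tied
    idx = np.concatenate([above, np.sort(chosen)]).astype(int)
    return InterventionSet(indices=tuple(int(i) for i in idx), k=k, provenance=provenance)


def top_k_sum(y_true, k: int) -> float:
    """Sum of the k largest observed counts (tie-invariant denominator)."""
    yt = np.asarray(y_true, dtype=float)
    if k == 0:
        return 0.0
    return float(np.sort(yt)[-k:].sum())


def _iset_indices(iset) -> np.ndarray:
    if isinstance(iset, InterventionSet):
        return np.asarray(iset.indices, dtype=int)
    return np.asarray(iset, dtype=int)


def bpr(y_true, iset) -> float:
    """Best possible reach of an intervention set against observed counts.

    Returns sum(y over I) / sum(y over hindsight top-K).  An all-zero
    observed vector makes the ratio vacuous; it is defined as 1.0 (any set
    reaches all zero reachable events) with a loud warning.
    """
    yt = np.asarray(y_true, dtype=float)
    if np.any(yt < 0):
        raise ValueError("observed counts must be >= 0")
    idx = _iset_indices(iset)
    if len(idx) > len(yt):
        raise ValueError("intervention set larger than the tract set")
    denom = top_k_sum(yt, len(idx))
    if denom == 0:
        warnings.warn("all-zero observed counts: BPR defined as 1.0", stacklevel=2)
        return 1.0
    return float(yt[idx].sum() / denom)


def reach_fraction_all(y_true, iset) -> float:
    """Alternative reach metric dividing by events over all S tracts.

    Always <= bpr on the same inputs, and its maximum fluctuates with the
    observed data, which motivates the top-K denominator of ``bpr``.
    """
    yt = np.asarray(y_true, dtype=float)
    if np.any(yt < 0):
        raise ValueError("observed counts must be >= 0")
    idx = _iset_indices(iset)
    total = yt.sum()
    if total == 0:
        warnings.warn("all-zero observed counts: reach fraction defined as 1.0", stacklevel=2)
        return 1.0
    return float(yt[idx].sum() / total)


class RandomBPR(NamedTuple):
    """Monte-Carlo and closed-form expected BPR of uniform random selection."""

    mc_mean: float
    closed_form: float
    mc_se: float
    n_draws: int


def expected_random_bpr(
    y_true,
    k: int,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> RandomBPR:
    """Expected BPR of a uniformly random K-subset of tracts.

    Used for uninformative models that rank all tracts equally (e.g. the
    all-zeros baseline).  By linearity of expectation over uniform
    inclusion the closed form is (k/S) * sum(y) / top_k_sum(y, k); the
    Monte-Carlo mean over ``n_draws`` uniform K-subsets is returned
    alongside for cross-checking.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    yt = np.asarray(y_true, dtype=float)
    if np.any(yt < 0):
        raise ValueError("observed counts must be >= 0")
    S = len(yt)
    if not (0 < k <= S):
        raise ValueError(f"k={k} outside [1, {S}]")
    denom = top_k_sum(yt, k)
    if denom == 0:
        warnings.warn("all-zero observed counts: BPR defined as 1.0", stacklevel=2)
        return RandomBPR(1.0, 1.0, 0.0, n_draws)
    closed = float((k / S) * yt.sum() / denom)

    if rng is None:
        rng = np.random.default_rng()
    vals = np.empty(n_draws)
    chunk = max(1, min(n_draws, int(2e7 // max(S, 1))))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        # uniform K-subsets via random-key argpartition
        keys = rng.random((m, S))
        sel = np.argpartition(keys, k - 1, axis=1)[:, :k]
        vals[done:done + m] = yt[sel].sum(axis=1) / denom
        done += m
    return RandomBPR(float(vals.mean()),
                     closed,
                     float(vals.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0,
                     n_draws)
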