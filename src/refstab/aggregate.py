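"""Consensus ranking via Cross-Entropy Monte Carlo footrule minimization.

Different stability statistics rank the same genes differently; a
consensus ordering delta minimizes the weighted total Spearman footrule
distance

    Phi(delta) = sum over lists l of  w_l * sum over items i of
                 |pos_delta(i) - pos_l(i)|

The Cross-Entropy (CE) optimizer maintains an item-by-position
probability matrix, samples candidate permutations from it, and
reinforces the positions used by the elite fraction of samples until the
best objective stops improving.  :func:`aggregate_exhaustive` enumerates
all permutations (factorial guard at 9 items) and serves as the exact
oracle for small instances.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np

from .core import PreconditionError

logger = logging.getLogger(__name__)

EXHAUSTIVE_GUARD = 9


@dataclasses.dataclass(frozen=True)
class RankedListSet:
    """k full orderings of one item set, with positive per-list weights."""

    lists: tuple
    weights: tuple

    @classmethod
    def from_lists(cls, lists, weights=None) -> "RankedListSet":
        lists = tuple(tuple(l) for l in lists)
        if not lists:
            raise PreconditionError("need at least one ranked list")
        base = set(lists[0])
        for l in lists:
            if len(set(l)) != len(l):
                raise PreconditionError(f"duplicate items in list {l!r}")
            if set(l) != base:
                raise PreconditionError("all lists must rank the same item set")
        if weights is None:
            weights = (1.0,) * len(lists)
        weights = tuple(float(w) for w in weights)
        if len(weights) != len(lists) or any(w <= 0 for w in weights):
            raise PreconditionError("weights must be positive, one per list")
        return cls(lists, weights)

    @property
    def items(self) -> tuple:
        return tuple(sorted(self.lists[0]))


@dataclasses.dataclass(frozen=True)
class AggregationResult:
    consensus: tuple
    objective: float
    trace: tuple  # best objective per iteration
    params: dict
    seed: int | None = None
    co_optimal: bool | None = None  # exhaustive only: other optima exist


def spearman_footrule(a, b) -> int:
    """Sum over items of |position in a - position in b| (1-based)."""
    a, b = tuple(a), tuple(b)
    if set(a) != set(b) or len(set(a)) != len(a) or len(a) != len(b):
        raise PreconditionError("orderings must be permutations of the same items")
    pos_b = {item: i for i, item in enumerate(b)}
    return int(sum(abs(i - pos_b[item]) for i, item in enumerate(a)))


def total_footrule(ordering, lists, weights=None) -> float:
    """Weighted total footrule of ``ordering`` against all lists."""
    rls = lists if isinstance(lists, RankedListSet) else RankedListSet.from_lists(lists, weights)
    return float(
        sum(w * spearman_footrule(ordering, l) for w, l in zip(rls.weights, rls.lists))
    )


def _positions(rls: RankedListSet) -> np.ndarray:
    """k x n matrix of 0-based item positions, items in sorted order."""
    items = rls.items
    index = {item: i for i, item in enumerate(items)}
    k, n = len(rls.lists), len(items)
    pos = np.empty((k, n), dtype=np.int64)
    for li, l in enumerate(rls.lists):
        for p, item in enumerate(l):
            pos[li, index[item]] = p
    return pos


def aggregate_exhaustive(lists, weights=None) -> AggregationResult:
    """Exact consensus by enumerating all permutations (<= 9 items).

    Ties resolve to the lexicographically smallest optimal permutation;
    co-optimality is reported and logged.
    """
    rls = lists if isinstance(lists, RankedListSet) else RankedListSet.from_lists(lists, weights)
    items = rls.items
    if len(items) > EXHAUSTIVE_GUARD:
        raise PreconditionError(
            f"{len(items)} items exceed the factorial guard "
            f"({EXHAUSTIVE_GUARD}); use aggregate_ce"
        )
    list_pos = _positions(rls)
    w = np.asarray(rls.weights)
    best, best_val, n_opt = None, math.inf, 0
    for perm in itertools.permutations(range(len(items))):
        item_pos = np.empty(len(items), dtype=np.int64)
        for p, i in enumerate(perm):
            item_pos[i] = p
        val = float((w * np.abs(item_pos[None, :] - list_pos).sum(axis=1)).sum())
        if val < best_val - 1e-12:
            best, best_val, n_opt = perm, val, 1
        elif abs(val - best_val) <= 1e-12:
            n_opt += 1
    if n_opt > 1:
        logger.info("exhaustive search found %d co-optimal orderings", n_opt)
    consensus = tuple(items[i] for i in best)
    return AggregationResult(
        consensus=consensus,
        objective=best_val,
        trace=(best_val,),
        params={"method": "exhaustive"},
        co_optimal=n_opt > 1,
    )


def _sample_permutations(p: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """Draw permutations position-by-position from the probability matrix.

    ``p[i, j]`` is the propensity of item i at position j; at each
    position, items still available are sampled proportionally.
    Returns an (n_samples, n) array of item indices by position.
    """
    n = p.shape[0]
    avail = np.ones((n_samples, n), dtype=bool)
    perms = np.empty((n_samples, n), dtype=np.int64)
    rows = np.arange(n_samples)
    for j in range(n):
        wgt = p[:, j][None, :] * avail
        totals = wgt.sum(axis=1)
        # guard against degenerate all-zero rows (cannot happen while the
        # matrix stays smoothed, but keeps sampling well-defined)
        dead = totals <= 0
        if dead.any():
            wgt[dead] = avail[dead].astype(float)
            totals = wgt.sum(axis=1)
        u = rng.random(n_samples) * totals
        cum = np.cumsum(wgt, axis=1)
        choice = np.argmax(cum > u[:, None], axis=1)
        perms[:, j] = choice
        avail[rows, choice] = False
    return perms


def aggregate_ce(
    lists,
    weights=None,
    n_samples: int | None = None,
    rho: float = 0.1,
    smoothing: float = 0.25,
    max_iter: int = 200,
    patience: int = 15,
    seed: int | None = None,
) -> AggregationResult:
    """Cross-Entropy Monte Carlo minimization of the total footrule.

    Each iteration draws ``n_samples`` permutations (default
    ``max(100, 10 n^2)``) by sequential sampling without replacement from
    an item-by-position probability matrix, scores them, and moves the
    matrix toward the empirical frequencies of the best ``ceil(rho *
    n_samples)`` samples with smoothing weight ``smoothing``.  Stops when
    the best objective has not improved for ``patience`` iterations, or
    at ``max_iter``.  Fully reproducible given ``seed``.
    """
    rls = lists if isinstance(lists, RankedListSet) else RankedListSet.from_lists(lists, weights)
    items = rls.items
    n = len(items)
    if n_samples is None:
        n_samples = max(100, 10 * n * n)
    if n_samples < 10:
        raise PreconditionError("n_samples must be at least 10")
    n_elite = math.ceil(rho * n_samples)
    if n_elite < 1:
        raise PreconditionError("rho * n_samples must be at least 1")
    if not 0 < smoothing <= 1:
        raise PreconditionError("smoothing must be in (0, 1]")
    rng = np.random.default_rng(seed)
    list_pos = _positions(rls)
    w = np.asarray(rls.weights)

    p = np.full((n, n), 1.0 / n)
    best_perm, best_val = None, math.inf
    trace = []
    stall = 0
    for _ in range(max_iter):
        perms = _sample_permutations(p, n_samples, rng)
        item_pos = np.empty_like(perms)
        item_pos[np.arange(n_samples)[:, None], perms] = np.arange(n)[None, :]
        scores = (
            np.abs(item_pos[:, None, :] - list_pos[None, :, :]).sum(axis=2) @ w
        )
        order = np.argsort(scores, kind="stable")
        elite = perms[order[:n_elite]]
        it_best = float(scores[order[0]])
        if it_best < best_val - 1e-12:
            best_val = it_best
            best_perm = perms[order[0]].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_val)
        if stall >= patience:
            break
        freq = np.zeros((n, n))
        np.add.at(freq, (elite.ravel(), np.tile(np.arange(n), n_elite)), 1.0)
        p = (1.0 - smoothing) * p + smoothing * freq / n_elite
    consensus = tuple(items[i] for i in best_perm)
    return AggregationResult(
        consensus=consensus,
        objective=best_val,
        trace=tuple(trace),
        params={
            "method": "ce",
            "n_samples": n_samples,
            "rho": rho,
            "smoothing": smoothing,
            "max_iter": max_iter,
            "patience": patience,
        },
        seed=seed,
    )
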