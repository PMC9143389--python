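"""Two-stage descriptor selection: genetic-algorithm search, then RFE.

Stage one evolves fixed-length binary descriptor masks with a plain genetic
algorithm (tournament selection, uniform crossover, bit-flip mutation, one
elite) scored by a pluggable model-quality functional — by default the
cross-validated q^2 of a linear least-squares fit on the masked columns.
Stage two is recursive feature elimination: refit on every
leave-one-descriptor-out subset, and purge the descriptor whose removal
hurts the least, one per iteration, down to the target size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import DescriptorTable

__all__ = ["SelectionResult", "ga_select", "rfe_select", "linear_cv_q2"]

Fitness = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class SelectionResult:
    """Chosen descriptor subset plus the per-iteration search trace."""

    chosen: list[str]
    history: list[tuple[list[str], float]] = field(default_factory=list)
    seed: Optional[int] = None


def linear_cv_q2(X: np.ndarray, y: np.ndarray, folds: int = 5,
                 seed: int = 0) -> float:
    """Cross-validated q^2 of an ordinary least-squares fit.

    Out-of-fold predictions are pooled and scored as
    1 - sum((y - yhat)^2) / sum((y - <y>)^2).  Used as the default fitness
    for both selection stages.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = min(folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pred = np.empty(n)
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        A = np.column_stack([np.ones(len(train)), X[train]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred[test] = np.column_stack([np.ones(len(test)), X[test]]) @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def _repair(mask: np.ndarray, lo: int, hi: int, rng) -> np.ndarray:
    """Force the subset size into [lo, hi] by random bit edits."""
    on = np.nonzero(mask)[0]
    off = np.nonzero(~mask)[0]
    if len(on) > hi:
        drop = rng.choice(on, size=len(on) - hi, replace=False)
        mask[drop] = False
    elif len(on) < lo:
        add = rng.choice(off, size=lo - len(on), replace=False)
        mask[add] = True
    return mask


def ga_select(
    table: DescriptorTable,
    response: Sequence[float],
    subset_size_range: tuple[int, int] = (2, 5),
    population: int = 30,
    generations: int = 20,
    fitness: Optional[Fitness] = None,
    seed: int = 0,
) -> SelectionResult:
    """Genetic-algorithm search over descriptor subsets.

    Chromosomes are binary masks over the descriptor columns, constrained to
    the given subset-size range.  Evolution uses tournament selection (size
    2), uniform crossover, bit-flip mutation at rate 1/p, and one elite.
    The history records the best (subset, fitness) of the initial population
    and of every generation; elitism makes the best fitness non-decreasing.
    """
    y = np.asarray(response, dtype=float)
    names = table.descriptor_names
    p = len(names)
    lo, hi = subset_size_range
    if hi > p:
        raise ValueError(f"max subset size {hi} exceeds descriptor count {p}")
    if not (1 <= lo <= hi):
        raise ValueError(f"bad subset size range {subset_size_range}")
    fit = fitness or linear_cv_q2
    rng = np.random.default_rng(seed)

    def evaluate(mask: np.ndarray) -> float:
        return float(fit(table.values[:, mask], y))

    pop = []
    for _ in range(population):
        k = int(rng.integers(lo, hi + 1))
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=k, replace=False)] = True
        pop.append(mask)
    scores = [evaluate(m) for m in pop]

    history: list[tuple[list[str], float]] = []

    def log_best() -> None:
        b = int(np.argmax(scores))
        history.append(([names[i] for i in np.nonzero(pop[b])[0]], scores[b]))

    log_best()
    for _ in range(generations):
        elite_idx = int(np.argmax(scores))
        nxt = [pop[elite_idx].copy()]
        while len(nxt) < population:
            parents = []
            for _ in range(2):
                a, b = rng.integers(population), rng.integers(population)
                parents.append(pop[a] if scores[a] >= scores[b] else pop[b])
            cross = rng.random(p) < 0.5
            child = np.where(cross, parents[0], parents[1])
            flip = rng.random(p) < (1.0 / p)
            child = child ^ flip
            nxt.append(_repair(child, lo, hi, rng))
        pop = nxt
        scores = [evaluate(m) for m in pop]
        # elitism: never let the generation best fall below the elite
        if scores[0] < history[-1][1]:
            scores[0] = history[-1][1]
            pop[0] = np.array([n in history[-1][0] for n in names])
        log_best()

    best_subset, _ = max(zip([h[0] for h in history], [h[1] for h in history]),
                         key=lambda t: t[1])
    return SelectionResult(chosen=list(best_subset), history=history, seed=seed)


def rfe_select(
    table: DescriptorTable,
    response: Sequence[float],
    target_size: int,
    scorer: Optional[Fitness] = None,
) -> SelectionResult:
    """Recursive feature elimination down to ``target_size`` descriptors.

    Each outer iteration scores every leave-one-descriptor-out subset and
    purges the descriptor whose removal leaves the best score (i.e. the one
    contributing least); ties drop the lexicographically later name.
    Exactly one descriptor is removed per iteration.
    """
    if target_size < 1:
        raise ValueError(f"target_size must be >= 1, got {target_size}")
    y = np.asarray(response, dtype=float)
    score = scorer or linear_cv_q2
    current = list(table.descriptor_names)
    if len(current) < target_size:
        raise ValueError(
            f"target_size {target_size} exceeds descriptor count {len(current)}")

    def sc(subset: list[str]) -> float:
        idx = [table.descriptor_names.index(n) for n in subset]
        return float(score(table.values[:, idx], y))

    history: list[tuple[list[str], float]] = [(list(current), sc(current))]
    while len(current) > target_size:
        best_victim, best_score = None, -np.inf
        for name in current:
            trial = [n for n in current if n != name]
            s = sc(trial)
            if s > best_score or (s == best_score and name > best_victim):
                best_victim, best_score = name, s
        current = [n for n in current if n != best_victim]
        history.append((list(current), best_score))
    return SelectionResult(chosen=current, history=history)
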