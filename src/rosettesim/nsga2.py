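"""A compact NSGA-II (elitist non-dominated sorting genetic algorithm).

Real-coded, bounded on [0, 1]^n: simulated binary crossover (SBX),
polynomial mutation, binary tournament selection on (rank, crowding
distance), and fast non-dominated sorting.  Deterministic for a fixed
numpy Generator.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["fast_non_dominated_sort", "crowding_distance", "nsga2"]


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] True when solution i dominates solution j (minimization)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=-1)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=-1)
    return le & lt


def fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition objective vectors into successive non-dominated fronts."""
    F = np.asarray(F, dtype=float)
    n = len(F)
    D = _domination_matrix(F)
    n_dominators = D.sum(axis=0).astype(int)
    fronts: list[np.ndarray] = []
    remaining = n_dominators.copy()
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.where((remaining == 0) & ~assigned)[0]
        if current.size == 0:  # numerical safety; cannot happen for finite F
            current = np.where(~assigned)[0]
        fronts.append(current)
        assigned[current] = True
        remaining = remaining - D[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front (larger = less crowded)."""
    F = np.asarray(F, dtype=float)
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        span = fk[-1] - fk[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return dist


def _ranks_and_crowding(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F), dtype=float)
    for r, front in enumerate(fast_non_dominated_sort(F)):
        ranks[front] = r
        crowd[front] = crowding_distance(F[front])
    return ranks, crowd


def _tournament(ranks, crowd, rng: np.random.Generator, n_pick: int) -> np.ndarray:
    n = len(ranks)
    a = rng.integers(0, n, n_pick)
    b = rng.integers(0, n, n_pick)
    better_a = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] > crowd[b]))
    return np.where(better_a, a, b)


def _sbx(parents_a, parents_b, rng, eta=15.0, prob=0.9):
    """Simulated binary crossover, variable-wise, bounded to [0, 1]."""
    x1, x2 = parents_a.copy(), parents_b.copy()
    do = rng.random(x1.shape) < 0.5
    do &= rng.random((len(x1), 1)) < prob
    u = rng.random(x1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    c1 = 0.5 * ((1 + beta) * x1 + (1 - beta) * x2)
    c2 = 0.5 * ((1 - beta) * x1 + (1 + beta) * x2)
    out1 = np.where(do, c1, x1)
    out2 = np.where(do, c2, x2)
    return np.clip(out1, 0.0, 1.0), np.clip(out2, 0.0, 1.0)


def _polynomial_mutation(X, rng, eta=20.0, prob=None):
    """Polynomial mutation bounded to [0, 1]."""
    X = X.copy()
    n, d = X.shape
    if prob is None:
        prob = 1.0 / d
    do = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    X[do] += delta[do]
    return np.clip(X, 0.0, 1.0)


def nsga2(
    evaluate: Callable[[np.ndarray], np.ndarray],
    n_var: int,
    pop_size: int,
    n_gen: int,
    rng: np.random.Generator,
    eta_crossover: float = 15.0,
    eta_mutation: float = 20.0,
    p_crossover: float = 0.9,
    p_mutation: float | None = None,
    callback: Callable[[np.ndarray, np.ndarray], None] | None = None,
    refine: Callable[[np.ndarray, np.ndarray, int], list | None] | None = None,
):
    """Minimize a vector-valued objective over [0, 1]^n_var.

    ``evaluate`` maps a (k, n_var) design matrix to a (k, n_obj) objective
    matrix.  ``callback(X, F)`` is invoked on every newly evaluated batch
    (used to census qualified settings across the whole run).  ``refine``,
    if given, is called after each generation's environmental selection with
    (X, F, generation) and may return a list of (genome, objectives) pairs
    (a memetic local-refinement step); they replace the most dominated, most
    crowded members of the population.  Returns the final population (X, F)
    and the indices of its first non-dominated front.
    """
    if pop_size < 8 or pop_size % 2:
        raise ValueError("population size must be an even number >= 8")
    X = rng.random((pop_size, n_var))
    F = np.asarray(evaluate(X), dtype=float)
    if callback is not None:
        callback(X, F)
    ranks, crowd = _ranks_and_crowding(F)
    for gen in range(n_gen):
        idx_a = _tournament(ranks, crowd, rng, pop_size // 2)
        idx_b = _tournament(ranks, crowd, rng, pop_size // 2)
        c1, c2 = _sbx(X[idx_a], X[idx_b], rng, eta_crossover, p_crossover)
        offspring = _polynomial_mutation(
            np.vstack([c1, c2]), rng, eta_mutation, p_mutation
        )
        F_off = np.asarray(evaluate(offspring), dtype=float)
        if callback is not None:
            callback(offspring, F_off)
        X_all = np.vstack([X, offspring])
        F_all = np.vstack([F, F_off])
        # environmental selection: fill by fronts, break ties by crowding
        fronts = fast_non_dominated_sort(F_all)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(F_all[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order[: pop_size - len(keep)]].tolist())
                break
        keep_arr = np.array(keep)
        X, F = X_all[keep_arr], F_all[keep_arr]
        ranks, crowd = _ranks_and_crowding(F)
        if refine is not None:
            injected = refine(X, F, gen + 1)
            if injected:
                # replace the worst members (highest rank, then most crowded)
                order = np.lexsort((-crowd, ranks))
                victims = order[::-1][: len(injected)]
                for v, (genome, fvals) in zip(victims, injected):
                    X[v] = genome
                    F[v] = fvals
                ranks, crowd = _ranks_and_crowding(F)
    pareto = fast_non_dominated_sort(F)[0]
    return X, F, pareto
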