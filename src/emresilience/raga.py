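"""Real-coded accelerating genetic algorithm (RAGA) over a box.

Maximizes a black-box objective f(x) on a product of intervals. Genes
live on [0, 1]^n and are decoded linearly into the current bounds,
x(j) = a(j) + z(j) * (b(j) - a(j)). Each generation:

1. evaluate the decoded population;
2. assign geometric rank fitness eval(rank i) = alpha (1 - alpha)^(i-1)
   (best rank first) and roulette-select N parents on the cumulative
   fitness;
3. arithmetic-blend crossover of randomly paired parents (probability
   Pc of entering the parent pool);
4. directional mutation: selected individuals move by M * d with d a
   uniformly random unit direction in gene space and M uniform (0, 1),
   clamped to the box;
5. elitist truncation: parents, offspring and mutants are pooled (the
   "3N progeny") and the best N survive.

Every ``acceleration_period`` generations the variable bounds shrink to
the envelope of the current elite decoded values and the non-elite part
of the population is re-initialized inside the tighter box — the
"acceleration" that gives the algorithm its name. The best-so-far
individual is carried in the population throughout, so the best
objective trace is non-decreasing, and the whole run is a deterministic
function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import GAConfig

#: relative width given to a collapsed (zero-width) accelerated interval
_COLLAPSE_WIDEN = 1e-6


@dataclass
class OptimizerResult:
    """Outcome of one RAGA run."""

    best_x: np.ndarray
    best_objective: float
    trace: np.ndarray
    n_accelerations: int
    final_bounds: np.ndarray
    n_generations: int

    def __post_init__(self) -> None:
        self.best_x = np.asarray(self.best_x, dtype=float)
        self.trace = np.asarray(self.trace, dtype=float)
        self.final_bounds = np.asarray(self.final_bounds, dtype=float)


def decode(z: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Map genes z in [0,1]^n onto the box: x(j) = a(j) + z(j)(b(j)-a(j))."""
    z = np.asarray(z, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("genes must lie in [0, 1]")
    lo, hi = bounds[..., 0], bounds[..., 1]
    return lo + z * (hi - lo)


def rank_fitness(objectives: np.ndarray, alpha: float) -> np.ndarray:
    """Geometric rank fitness, best objective first.

    The rank-i individual (1-based, descending objective, ties kept in
    input order) receives alpha * (1 - alpha)^(i-1). Returned in the
    input order of ``objectives``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    objectives = np.asarray(objectives, dtype=float)
    order = np.argsort(-objectives, kind="stable")
    fitness = np.empty_like(objectives)
    fitness[order] = alpha * (1.0 - alpha) ** np.arange(objectives.size)
    return fitness


def roulette_select(
    fitness: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative-probability roulette selection of ``count`` indices.

    Draws r uniform on (0, q_N] with q the cumulative fitness and picks
    the i with q_{i-1} < r <= q_i.
    """
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness <= 0):
        raise ValueError("all fitness values must be positive")
    q = np.cumsum(fitness)
    r = rng.uniform(0.0, q[-1], size=count)
    return np.searchsorted(q, r, side="left").astype(int)


def blend_pair(
    p1: np.ndarray, p2: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic per-gene blend: children u*p1 + (1-u)*p2 and complement."""
    c1 = u * p1 + (1.0 - u) * p2
    c2 = (1.0 - u) * p1 + u * p2
    return np.clip(c1, 0.0, 1.0), np.clip(c2, 0.0, 1.0)


def crossover(genes: np.ndarray, pc: float, rng: np.random.Generator) -> np.ndarray:
    """Arithmetic-blend crossover of the parent pool.

    Each individual enters the parent pool with probability ``pc``;
    pool members are randomly paired and each pair yields two children.
    Returns the (possibly empty) offspring gene matrix.
    """
    genes = np.asarray(genes, dtype=float)
    n_ind, n_genes = genes.shape
    chosen = np.nonzero(rng.uniform(size=n_ind) < pc)[0]
    if chosen.size < 2:
        return np.empty((0, n_genes))
    perm = rng.permutation(chosen)
    n_pairs = perm.size // 2
    children = np.empty((2 * n_pairs, n_genes))
    for k in range(n_pairs):
        u = rng.uniform(size=n_genes)
        c1, c2 = blend_pair(genes[perm[2 * k]], genes[perm[2 * k + 1]], u)
        children[2 * k] = c1
        children[2 * k + 1] = c2
    return children


def mutate(genes: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    """Directional mutation: x + M * d, d uniform on the unit sphere.

    Each individual mutates with probability ``pm``; M is uniform on
    (0, 1); mutants are clamped to the unit box.
    """
    genes = np.asarray(genes, dtype=float)
    n_ind, n_genes = genes.shape
    chosen = np.nonzero(rng.uniform(size=n_ind) < pm)[0]
    mutants = np.empty((chosen.size, n_genes))
    for k, i in enumerate(chosen):
        d = rng.standard_normal(n_genes)
        norm = np.linalg.norm(d)
        while norm < 1e-12:  # astronomically rare; redraw for safety
            d = rng.standard_normal(n_genes)
            norm = np.linalg.norm(d)
        step = rng.uniform() * d / norm
        mutants[k] = np.clip(genes[i] + step, 0.0, 1.0)
    return mutants


def accelerate(
    elite_decoded: np.ndarray,
    current_bounds: np.ndarray,
    original_span: np.ndarray,
    min_width_fraction: float = 0.5,
) -> np.ndarray:
    """Shrink bounds toward the elite envelope, never widening them.

    The raw envelope [min, max] of the elite decoded values contracts
    far too fast once the population has clustered, freezing the search
    box before it has migrated onto the optimum; the new interval is
    therefore floored at ``min_width_fraction`` of the current width,
    centered on the envelope and slid back inside the current bounds.
    With ``min_width_fraction = 0`` the rule is the pure envelope, a
    collapsed interval (all elites at one point) then being widened
    symmetrically by 1e-6 of the original span so the search can still
    move.
    """
    elite_decoded = np.atleast_2d(np.asarray(elite_decoded, dtype=float))
    if elite_decoded.size == 0:
        raise ValueError("elite set must be non-empty")
    current_bounds = np.asarray(current_bounds, dtype=float)
    cur_lo, cur_hi = current_bounds[:, 0], current_bounds[:, 1]
    lo = np.maximum(elite_decoded.min(axis=0), cur_lo)
    hi = np.minimum(elite_decoded.max(axis=0), cur_hi)
    if min_width_fraction > 0:
        floor = min_width_fraction * (cur_hi - cur_lo)
        grow = np.maximum(floor - (hi - lo), 0.0) / 2.0
        lo, hi = lo - grow, hi + grow
        # slide the interval back inside the current bounds
        shift = np.maximum(cur_lo - lo, 0.0) - np.maximum(hi - cur_hi, 0.0)
        lo = np.maximum(lo + shift, cur_lo)
        hi = np.minimum(hi + shift, cur_hi)
    else:
        collapsed = hi - lo <= 0
        pad = _COLLAPSE_WIDEN * np.asarray(original_span, dtype=float)
        lo = np.where(collapsed, lo - pad, lo)
        hi = np.where(collapsed, hi + pad, hi)
    return np.column_stack([lo, hi])


def optimize(
    objective_fn: Callable[[np.ndarray], float], n: int, cfg: GAConfig
) -> OptimizerResult:
    """Run the accelerating GA; maximize ``objective_fn`` over the box.

    ``objective_fn`` must be total on the (initial) box. The run stops
    at ``cfg.max_iterations`` generations or when the best objective has
    improved by less than ``cfg.stagnation_tol`` over
    ``cfg.stagnation_window`` generations.
    """
    rng = np.random.default_rng(cfg.seed)
    N = cfg.population_size

    if cfg.bounds is not None:
        bounds = np.asarray(cfg.bounds, dtype=float)
        if bounds.shape != (n, 2):
            raise ValueError(f"bounds must have shape ({n}, 2), got {bounds.shape}")
        bounds = bounds.copy()
    else:
        bounds = np.tile([0.0, 1.0], (n, 1))
    original_span = bounds[:, 1] - bounds[:, 0]

    n_elite = max(1, math.ceil(cfg.elite_fraction * N))

    genes = rng.uniform(size=(N, n))
    best_obj = -np.inf
    best_gene = genes[0].copy()
    best_x = decode(best_gene, bounds)
    trace: list[float] = []
    n_acc = 0

    gen = 0
    for gen in range(1, cfg.max_iterations + 1):
        decoded = decode(genes, bounds)
        obj = np.array([objective_fn(x) for x in decoded])

        gbest = int(np.argmax(obj))
        if obj[gbest] > best_obj:
            best_obj = float(obj[gbest])
            best_gene = genes[gbest].copy()
            best_x = decoded[gbest].copy()
        trace.append(best_obj)

        if (
            len(trace) > cfg.stagnation_window
            and trace[-1] - trace[-1 - cfg.stagnation_window] < cfg.stagnation_tol
        ):
            break

        fitness = rank_fitness(obj, cfg.selection_pressure)
        sel = roulette_select(fitness, N, rng)
        parents = genes[sel]
        parent_obj = obj[sel]

        offspring = crossover(parents, cfg.crossover_prob, rng)
        mutants = mutate(parents, cfg.mutation_prob, rng)

        new = np.vstack([offspring, mutants]) if offspring.size or mutants.size else np.empty((0, n))
        if new.shape[0]:
            new_obj = np.array([objective_fn(x) for x in decode(new, bounds)])
        else:
            new_obj = np.empty(0)

        # pool parents + offspring + mutants + the best-so-far individual,
        # keep the best N (elitist truncation)
        pool = np.vstack([parents, new, best_gene[None, :]])
        pool_obj = np.concatenate([parent_obj, new_obj, [best_obj]])
        keep = np.argsort(-pool_obj, kind="stable")[:N]
        genes = pool[keep]
        pop_obj = pool_obj[keep]

        if gen % cfg.acceleration_period == 0:
            elite_idx = np.argsort(-pop_obj, kind="stable")[:n_elite]
            elite_decoded = decode(genes[elite_idx], bounds)
            new_bounds = accelerate(
                elite_decoded, bounds, original_span, cfg.acceleration_min_width
            )
            span = new_bounds[:, 1] - new_bounds[:, 0]
            # re-encode elites in the shrunken box, refresh the rest
            re_enc = np.clip(
                (elite_decoded - new_bounds[:, 0]) / span, 0.0, 1.0
            )
            fresh = rng.uniform(size=(N - n_elite, n))
            genes = np.vstack([re_enc, fresh])
            bounds = new_bounds
            best_gene = np.clip((best_x - bounds[:, 0]) / span, 0.0, 1.0)
            n_acc += 1

    return OptimizerResult(
        best_x=best_x,
        best_objective=best_obj,
        trace=np.asarray(trace),
        n_accelerations=n_acc,
        final_bounds=bounds,
        n_generations=gen,
    )
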