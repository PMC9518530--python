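"""Composite-index weighting, region scoring, classification, comparator.

The projection-pursuit model is run in two orientations on the same
standardized panel:

* **index weighting** — the transposed matrix (indicators as
  observation rows, regions as variables) yields one optimal projection
  value per indicator; these projection values are reported raw and,
  normalized to sum to one, as the indicator weights;
* **region scoring** — the matrix in its natural orientation (regions
  as observation rows, indicators as variables) yields one optimal
  projection value per region, the composite resilience score.

Scores are also computed per capacity dimension on that dimension's
indicator subset alone; the composite score is deliberately *not* the
weighted mean of the dimension scores (the report records both and
their difference). Region scores are stratified into k classes with
exact Jenks natural breaks, level 1 being the highest class. An
entropy-weighted TOPSIS run on the same standardized panel serves as an
independent comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .core import (
    ClassificationResult,
    DIMENSIONS,
    DegenerateColumnError,
    GAConfig,
    ProjectionSolution,
    StandardizedPanel,
)
from .projection import ObjectiveSpec, objective
from .raga import optimize

#: per-dimension iteration defaults for the dimension-wise runs
DIMENSION_ITERATIONS = {
    "resistance": 15,
    "restore": 200,
    "adaptability": 400,
    "collaborative": 150,
}


class DegenerateSpreadError(ValueError):
    """No direction separates the observations (objective identically 0)."""


def _ppm_optimize(X: np.ndarray, cfg: GAConfig) -> ProjectionSolution:
    """Maximize the projection index over unit directions via RAGA.

    Candidate gene vectors are decoded into the configured box
    ([0, 1]^n by default, [-1, 1]^n in signed mode) and renormalized to
    the unit sphere inside the objective, enforcing the constraint
    exactly.
    """
    X = np.asarray(X, dtype=float)
    n_vars = X.shape[1]
    spec = ObjectiveSpec(
        data=X,
        radius_rule=cfg.density_radius_rule,
        radius_value=cfg.density_radius_value,
        include_self_pairs=cfg.include_self_pairs,
    )

    def fn(x: np.ndarray) -> float:
        if np.linalg.norm(x) < 1e-12:
            return -1.0  # degenerate candidate, rank below any feasible F >= 0
        return objective(spec, x)[0]

    run_cfg = cfg
    if cfg.bounds is None and not cfg.nonnegative_directions:
        run_cfg = cfg.replace(bounds=[(-1.0, 1.0)] * n_vars)

    result = optimize(fn, n_vars, run_cfg)
    direction = result.best_x
    norm = np.linalg.norm(direction)
    # rounding noise can lift an identically-zero objective to ~1e-33
    if norm < 1e-12 or result.best_objective <= 1e-12:
        raise DegenerateSpreadError(
            "projection pursuit found no direction with positive objective; "
            "the observations are indistinguishable"
        )
    direction = direction / norm
    F, S, D, R = objective(spec, direction)
    return ProjectionSolution(
        direction=direction,
        projections=X @ direction,
        objective=F,
        spread=S,
        density=D,
        radius=R,
        trace=result.trace,
    )


def index_weights(
    std: StandardizedPanel, cfg: GAConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-indicator optimal projection values and normalized weights.

    Runs the optimizer on the transposed standardized matrix (indicator
    rows as observations). Returns ``(projection_values, weights)``
    where ``weights`` is ``projection_values`` scaled to sum to one.
    """
    sol = index_weights_solution(std, cfg)
    return sol.projections, _normalize_weights(sol.projections)


def index_weights_solution(std: StandardizedPanel, cfg: GAConfig) -> ProjectionSolution:
    """Full projection solution of the index-weighting orientation."""
    return _ppm_optimize(std.values.T, cfg)


def _normalize_weights(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise DegenerateSpreadError("projection values sum to zero; cannot normalize")
    return values / total


def resilience_scores(std: StandardizedPanel, cfg: GAConfig) -> np.ndarray:
    """Composite resilience score per region (natural orientation)."""
    return resilience_scores_solution(std, cfg).projections


def resilience_scores_solution(std: StandardizedPanel, cfg: GAConfig) -> ProjectionSolution:
    """Full projection solution of the region-scoring orientation."""
    return _ppm_optimize(std.values, cfg)


def dimension_scores(
    std: StandardizedPanel,
    dimension: str,
    cfg: GAConfig,
    iterations: Optional[int] = None,
) -> np.ndarray:
    """Region scores using only one dimension's indicators.

    ``iterations`` defaults to the dimension-specific counts in
    :data:`DIMENSION_ITERATIONS`.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    cols = std.dimension_columns(dimension)
    if len(cols) < 2:
        raise ValueError(
            f"dimension {dimension!r} has {len(cols)} indicator(s); need at least 2"
        )
    if iterations is None:
        iterations = DIMENSION_ITERATIONS[dimension]
    sub_cfg = cfg.replace(max_iterations=iterations)
    return resilience_scores(std.subset(cols), sub_cfg)


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def _class_sse(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """SSE of sorted[i..j] (inclusive) from prefix sums."""
    n = j - i + 1
    s = prefix[j + 1] - prefix[i]
    sq = prefix_sq[j + 1] - prefix_sq[i]
    return sq - s * s / n


def jenks_breaks(values: np.ndarray, k: int) -> ClassificationResult:
    """Exact Jenks natural-breaks classification into k classes.

    Dynamic programming over the sorted values finds the contiguous
    partition minimizing the within-class sum of squared deviations
    (the global optimum, not a heuristic). ``breaks`` are the k-1
    minima of the upper classes, so a value belongs to the class whose
    lower bound it meets; ``labels`` use level 1 for the highest class.
    """
    values = np.asarray(values, dtype=float)
    m = values.size
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if k < 2:
        raise ValueError("k must be >= 2")
    if m < k:
        raise ValueError(f"cannot split {m} values into {k} classes")
    n_distinct = np.unique(values).size
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({n_distinct})"
        )

    s = np.sort(values)
    prefix = np.concatenate([[0.0], np.cumsum(s)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(s * s)])

    # cost[c][j]: min within-class SSE of s[0..j] split into c+1 classes
    cost = np.full((k, m), np.inf)
    cut = np.zeros((k, m), dtype=int)
    for j in range(m):
        cost[0, j] = _class_sse(prefix, prefix_sq, 0, j)
    for c in range(1, k):
        for j in range(c, m):
            # last class starts at i in [c, j]
            best, best_i = np.inf, c
            for i in range(c, j + 1):
                v = cost[c - 1, i - 1] + _class_sse(prefix, prefix_sq, i, j)
                if v < best:
                    best, best_i = v, i
            cost[c, j] = best
            cut[c, j] = best_i

    # recover class start indices
    starts = [0] * k
    j = m - 1
    for c in range(k - 1, 0, -1):
        starts[c] = int(cut[c, j])
        j = starts[c] - 1

    breaks = np.array([s[starts[c]] for c in range(1, k)])
    sse_within = float(cost[k - 1, m - 1])
    sse_total = float(_class_sse(prefix, prefix_sq, 0, m - 1))
    gvf = 1.0 if sse_total == 0 else 1.0 - sse_within / sse_total

    labels = assign_levels(values, breaks)
    return ClassificationResult(k=k, breaks=breaks, labels=labels, gvf=gvf)


def assign_levels(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Map values to levels; level 1 iff value >= top break.

    Interior classes are left-closed right-open going downward: with
    breaks (b1 < ... < b_{k-1}), level j (1 < j < k) holds values in
    [b_{k-j}, b_{k-j+1}), and level k values below b1.
    """
    values = np.asarray(values, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly ascending")
    k = breaks.size + 1
    return (k - np.searchsorted(breaks, values, side="right")).astype(int)


def jenks_breaks_bruteforce(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exhaustive search over all contiguous partitions (oracle; small m).

    Returns the optimal breaks and within-class SSE. Exponential in m;
    intended for cross-checking :func:`jenks_breaks` on toy inputs.
    """
    values = np.asarray(values, dtype=float)
    s = np.sort(values)
    m = s.size
    prefix = np.concatenate([[0.0], np.cumsum(s)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(s * s)])
    best_sse, best_cuts = np.inf, None
    for cuts in combinations(range(1, m), k - 1):
        edges = (0,) + cuts + (m,)
        sse = sum(
            _class_sse(prefix, prefix_sq, edges[c], edges[c + 1] - 1)
            for c in range(k)
        )
        if sse < best_sse - 1e-15:
            best_sse, best_cuts = sse, cuts
    breaks = np.array([s[c] for c in best_cuts])
    return breaks, float(best_sse)


# ---------------------------------------------------------------------------
# Entropy-TOPSIS comparator
# ---------------------------------------------------------------------------

def entropy_topsis(std: StandardizedPanel) -> tuple[np.ndarray, np.ndarray]:
    """Entropy weights and TOPSIS closeness on the standardized panel.

    The entropy of indicator j is e_j = -(1/ln m) * sum_i p_ij ln p_ij
    with p_ij the column-normalized shares (zero shares contribute 0);
    weights are (1 - e_j) / sum_k (1 - e_k). Closeness is
    d- / (d+ + d-), the relative distance to the weighted anti-ideal.
    """
    X = np.asarray(std.values, dtype=float)
    m, n = X.shape
    col_sum = X.sum(axis=0)
    if np.any(col_sum <= 0):
        j = int(np.nonzero(col_sum <= 0)[0][0])
        raise DegenerateColumnError(
            f"column {std.scheme[j].code!r} sums to zero; entropy undefined"
        )
    P = X / col_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    d = 1.0 - e
    if d.sum() <= 0:
        raise DegenerateColumnError("all columns at maximum entropy; weights undefined")
    w = d / d.sum()

    V = X * w
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    d_plus = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - anti) ** 2).sum(axis=1))
    closeness = d_minus / (d_plus + d_minus)
    return w, closeness


# ---------------------------------------------------------------------------
# Full measurement report
# ---------------------------------------------------------------------------

@dataclass
class MeasureReport:
    """Everything one measurement run produces.

    ``dimension_weighted_mean`` is the per-region weighted mean of the
    four dimension scores (weights = each dimension's share of the
    normalized index weights); ``non_additivity`` its difference from
    the all-indicator composite score — reported as an observation,
    never enforced.
    """

    region_labels: list[str]
    indicator_codes: list[str]
    index_projection_values: np.ndarray
    index_weights: np.ndarray
    region_scores: np.ndarray
    dimension_scores: dict[str, np.ndarray]
    dimension_weighted_mean: np.ndarray
    non_additivity: np.ndarray
    classification: ClassificationResult
    comparator_weights: Optional[np.ndarray] = None
    comparator_scores: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region_labels": list(self.region_labels),
            "indicator_codes": list(self.indicator_codes),
            "index_projection_values": self.index_projection_values.tolist(),
            "index_weights": self.index_weights.tolist(),
            "region_scores": self.region_scores.tolist(),
            "dimension_scores": {k: v.tolist() for k, v in self.dimension_scores.items()},
            "dimension_weighted_mean": self.dimension_weighted_mean.tolist(),
            "non_additivity": self.non_additivity.tolist(),
            "classification": self.classification.to_dict(),
            "comparator_weights": (
                None if self.comparator_weights is None else self.comparator_weights.tolist()
            ),
            "comparator_scores": (
                None if self.comparator_scores is None else self.comparator_scores.tolist()
            ),
            "config": self.config,
        }


def run_measure(
    std: StandardizedPanel,
    cfg: GAConfig,
    *,
    k: int = 5,
    dimension_iterations: Optional[dict[str, int]] = None,
    comparator: bool = True,
    stage_seeds: Optional[dict[str, int]] = None,
) -> MeasureReport:
    """Run both orientations, dimension runs, classification, comparator.

    ``stage_seeds`` optionally overrides the GA seed per stage (keys:
    ``weights``, ``scores``, and each dimension name); by default every
    stage derives a distinct deterministic seed from ``cfg.seed``.
    """
    if stage_seeds is None:
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(2 + len(DIMENSIONS))
        names = ["weights", "scores", *DIMENSIONS]
        stage_seeds = {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    proj_values, weights = index_weights(std, cfg.replace(seed=stage_seeds["weights"]))
    scores = resilience_scores(std, cfg.replace(seed=stage_seeds["scores"]))

    dim_scores: dict[str, np.ndarray] = {}
    dim_weight = np.zeros(len(DIMENSIONS))
    for d_idx, dim in enumerate(DIMENSIONS):
        iters = None if dimension_iterations is None else dimension_iterations.get(dim)
        dim_scores[dim] = dimension_scores(
            std, dim, cfg.replace(seed=stage_seeds[dim]), iterations=iters
        )
        dim_weight[d_idx] = weights[std.dimension_columns(dim)].sum()

    dim_matrix = np.column_stack([dim_scores[d] for d in DIMENSIONS])
    weighted_mean = dim_matrix @ (dim_weight / dim_weight.sum())
    classification = jenks_breaks(scores, k)

    comp_w = comp_s = None
    if comparator:
        comp_w, comp_s = entropy_topsis(std)

    return MeasureReport(
        region_labels=list(std.region_labels),
        indicator_codes=std.codes,
        index_projection_values=proj_values,
        index_weights=weights,
        region_scores=scores,
        dimension_scores=dim_scores,
        dimension_weighted_mean=weighted_mean,
        non_additivity=scores - weighted_mean,
        classification=classification,
        comparator_weights=comp_w,
        comparator_scores=comp_s,
        config={"seed": cfg.seed, "stage_seeds": stage_seeds, "k": k},
    )
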