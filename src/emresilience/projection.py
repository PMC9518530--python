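"""The projection-pursuit index: projections, spread, density, objective.

A candidate direction ``a`` (unit Euclidean norm) projects the m
standardized observation rows onto a scalar axis,
``y(i) = sum_j a(j) x(i, j)``. The interestingness of a direction is

    F(a) = S_y * D_y

where ``S_y`` is the sample standard deviation of the projections
(between-group spread) and ``D_y`` a within-window pairwise density

    D_y = sum_{i != j} (R - r_ij) * u(R - r_ij),   r_ij = |y_i - y_j|,

with ``u`` the unit step (u(t) = 1 for t >= 0). Maximizing F pulls the
projected points into tight local clusters that are far apart overall.
The window radius R defaults to a fixed fraction of the spread
(R = 0.1 * S_y), the common convention for this index; a fixed radius
is available. Self-pairs (i = j) each contribute exactly R and are
excluded by default since under the fraction rule their total m * R
varies with the direction and distorts the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRACTION_OF_SPREAD = "fraction_of_spread"
FIXED = "fixed"


class ZeroDirectionError(ValueError):
    """The candidate projection direction has (near-)zero norm."""


@dataclass
class ObjectiveSpec:
    """A frozen objective: the data matrix plus the radius convention."""

    data: np.ndarray
    radius_rule: str = FRACTION_OF_SPREAD
    radius_value: float = 0.1
    include_self_pairs: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.radius_rule not in (FRACTION_OF_SPREAD, FIXED):
            raise ValueError(
                f"radius_rule must be '{FRACTION_OF_SPREAD}' or '{FIXED}'"
            )
        if self.radius_value <= 0:
            raise ValueError("radius_value must be positive")


def project(X: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto direction ``a``: y(i) = sum_j a(j) x(i,j)."""
    X = np.asarray(X, dtype=float)
    a = np.asarray(a, dtype=float)
    if X.ndim != 2 or a.ndim != 1 or X.shape[1] != a.shape[0]:
        raise ValueError(
            f"dimension mismatch: X is {X.shape}, a has {a.shape[0]} components"
        )
    return X @ a


def spread(y: np.ndarray) -> float:
    """Sample standard deviation of the projections, (m - 1) denominator."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("spread requires at least 2 projected values")
    return float(np.std(y, ddof=1))


def local_density(y: np.ndarray, R: float, include_self: bool = False) -> float:
    """Window density over ordered pairs of projected values.

    Each ordered pair (i, j) with |y_i - y_j| <= R contributes
    R - |y_i - y_j|; a pair exactly at distance R contributes zero
    weight (the step function is 1 there, the triangular weight 0).
    Self-pairs each add R when ``include_self``.
    """
    y = np.asarray(y, dtype=float)
    if R <= 0:
        raise ValueError("R must be positive")
    r = np.abs(y[:, None] - y[None, :])
    within = r <= R
    contrib = (R - r) * within
    total = float(contrib.sum())
    if not include_self:
        total -= R * y.size  # remove the diagonal's m * R
    return total


def objective(spec: ObjectiveSpec, a: np.ndarray) -> tuple[float, float, float, float]:
    """Evaluate F(a) = S_y * D_y; returns (F, S_y, D_y, R).

    The direction is renormalized to unit norm internally, so the
    unit-sphere constraint is enforced exactly rather than by penalty.
    """
    a = np.asarray(a, dtype=float)
    norm = float(np.linalg.norm(a))
    if norm < 1e-12:
        raise ZeroDirectionError("projection direction has zero norm")
    a = a / norm

    y = project(spec.data, a)
    S = spread(y)
    if S == 0.0:
        # all projections coincide: no structure in this direction
        return 0.0, 0.0, 0.0, 0.0
    R = spec.radius_value * S if spec.radius_rule == FRACTION_OF_SPREAD else spec.radius_value
    D = local_density(y, R, include_self=spec.include_self_pairs)
    return float(S * D), S, D, R
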