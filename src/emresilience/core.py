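"""Shared domain types and validation for composite resilience measurement.

The package evaluates a region x indicator panel: ``m`` administrative
regions described by ``n`` heterogeneous indicators grouped into four
capacity dimensions (resistance, restore, adaptability, collaborative).
Every downstream stage (imputation, standardization, projection-pursuit
weighting, classification, spatial autocorrelation) consumes or produces
the types defined here.

Conventions
-----------
* Matrices are addressed (region-row, indicator-column); region and
  indicator order is significant and preserved everywhere.
* Classification levels are numbered 1 = highest-value class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The four capacity dimensions of the composite resilience index.
DIMENSIONS = ("resistance", "restore", "adaptability", "collaborative")

ATTRIBUTES = ("positive", "negative")


class PanelError(ValueError):
    """Base class for panel-validation failures."""


class IncompletePanelError(PanelError):
    """An operation requiring a complete panel received missing cells."""


class DegenerateColumnError(PanelError):
    """A constant indicator column cannot be min-max standardized."""


class InsufficientDataError(PanelError):
    """Too few observed values to fit the imputation model."""


class ZeroVarianceError(ValueError):
    """A spatially analyzed attribute is constant across regions."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """One measurement indicator of the composite index.

    Parameters
    ----------
    code : str
        Short identifier, e.g. ``"V11"``. Unique within a scheme.
    dimension : str
        One of :data:`DIMENSIONS`.
    attribute : str
        ``"positive"`` if larger raw values mean better status,
        ``"negative"`` if larger raw values mean worse status. The
        attribute decides the orientation branch of min-max
        standardization.
    description, units : str
        Free-text documentation.
    """

    code: str
    dimension: str
    attribute: str
    description: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(
                f"unknown dimension {self.dimension!r}; expected one of {DIMENSIONS}"
            )
        if self.attribute not in ATTRIBUTES:
            raise ValueError(
                f"attribute must be one of {ATTRIBUTES}, got {self.attribute!r}"
            )


@dataclass
class IndicatorPanel:
    """Region x indicator table of raw values with an explicit missing mask.

    ``values[i, j]`` is the raw measurement of indicator ``scheme[j]``
    for region ``region_labels[i]``; cells flagged in ``missing_mask``
    hold NaN and are ignored by every computation until imputed.
    """

    region_labels: list[str]
    scheme: list[IndicatorDefinition]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.region_labels = list(self.region_labels)
        self.scheme = list(self.scheme)

    # -- shape helpers -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @property
    def codes(self) -> list[str]:
        return [d.code for d in self.scheme]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def dimension_columns(self, dimension: str) -> list[int]:
        """Column indices of all indicators belonging to ``dimension``."""
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return [j for j, d in enumerate(self.scheme) if d.dimension == dimension]

    def copy(self) -> "IndicatorPanel":
        return IndicatorPanel(
            list(self.region_labels),
            list(self.scheme),
            self.values.copy(),
            self.missing_mask.copy(),
        )


@dataclass
class StandardizedPanel:
    """Panel after attribute-oriented min-max standardization.

    All values lie in [0, 1]; per column the extremes 0 and 1 are
    attained (larger always means better, negative indicators having
    been flipped). ``col_min``/``col_max`` record the raw extremes used,
    so the transform is auditable and invertible for positive columns.
    """

    region_labels: list[str]
    scheme: list[IndicatorDefinition]
    values: np.ndarray
    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.col_min = np.asarray(self.col_min, dtype=float)
        self.col_max = np.asarray(self.col_max, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @property
    def codes(self) -> list[str]:
        return [d.code for d in self.scheme]

    def dimension_columns(self, dimension: str) -> list[int]:
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return [j for j, d in enumerate(self.scheme) if d.dimension == dimension]

    def subset(self, columns: Sequence[int]) -> "StandardizedPanel":
        """Restriction to a column subset (e.g. one dimension)."""
        cols = list(columns)
        return StandardizedPanel(
            list(self.region_labels),
            [self.scheme[j] for j in cols],
            self.values[:, cols].copy(),
            self.col_min[cols].copy(),
            self.col_max[cols].copy(),
        )


@dataclass
class GAConfig:
    """Hyperparameters of the real-coded accelerating genetic algorithm.

    Defaults follow the index-weighting configuration of the study this
    framework implements: population 40, crossover probability 0.8,
    mutation probability 0.2, 250 iterations.

    ``selection_pressure`` is the alpha of the geometric rank-fitness
    eval(rank i) = alpha * (1 - alpha)^(i-1). ``acceleration_period``
    controls how often the variable bounds are shrunk around the current
    elite envelope; ``elite_fraction`` how many individuals define it.
    ``density_radius_rule``/``density_radius_value`` parameterize the
    projection-index window radius R (``fraction_of_spread`` sets
    R = value * S_y).
    """

    population_size: int = 40
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    selection_pressure: float = 0.05
    max_iterations: int = 250
    acceleration_period: int = 5
    acceleration_min_width: float = 0.5
    elite_fraction: float = 0.2
    bounds: Optional[Sequence[tuple[float, float]]] = None
    density_radius_rule: str = "fraction_of_spread"
    density_radius_value: float = 0.1
    include_self_pairs: bool = False
    nonnegative_directions: bool = True
    stagnation_tol: float = 1e-10
    stagnation_window: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 < self.selection_pressure < 1.0:
            raise ValueError("selection_pressure must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.acceleration_period < 1:
            raise ValueError("acceleration_period must be positive")
        if not 0.0 <= self.acceleration_min_width < 1.0:
            raise ValueError("acceleration_min_width must lie in [0, 1)")
        if not 0.0 < self.elite_fraction <= 1.0:
            raise ValueError("elite_fraction must lie in (0, 1]")
        if self.density_radius_rule not in ("fraction_of_spread", "fixed"):
            raise ValueError(
                "density_radius_rule must be 'fraction_of_spread' or 'fixed'"
            )
        if self.density_radius_value <= 0:
            raise ValueError("density_radius_value must be positive")
        if self.bounds is not None:
            for a, b in self.bounds:
                if not a < b:
                    raise ValueError(f"bounds must satisfy a < b, got ({a}, {b})")

    def replace(self, **kwargs) -> "GAConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ProjectionSolution:
    """Optimal projection found for one observation matrix.

    ``direction`` is the unit-norm projection direction a*, and
    ``projections`` the projected values y*(i) of each observation row.
    ``objective`` = ``spread`` * ``density`` recomputed at a*.
    """

    direction: np.ndarray
    projections: np.ndarray
    objective: float
    spread: float
    density: float
    radius: float
    trace: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.projections = np.asarray(self.projections, dtype=float)
        self.trace = np.asarray(self.trace, dtype=float)


@dataclass
class SpatialWeights:
    """Pairwise spatial weight matrix over labelled regions.

    ``matrix[i, j]`` is the weight of region j in the neighborhood of
    region i; the diagonal is zero. If ``standardized`` each nonzero
    row sums to one.
    """

    labels: list[str]
    matrix: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = list(self.labels)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.matrix.sum())

    def row_standardized(self) -> "SpatialWeights":
        """Return a copy with each nonzero row scaled to sum to one."""
        m = self.matrix.copy()
        sums = m.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        m[nz] = m[nz] / sums[nz]
        return SpatialWeights(list(self.labels), m, standardized=True)

    def subset(self, indices: Sequence[int]) -> "SpatialWeights":
        """Weights restricted to a region subset (re-standardized if needed)."""
        idx = list(indices)
        sub = SpatialWeights(
            [self.labels[i] for i in idx],
            self.matrix[np.ix_(idx, idx)].copy(),
            standardized=False,
        )
        if self.standardized:
            return sub.row_standardized()
        return sub


@dataclass
class GlobalMoranResult:
    """Global Moran's I with analytic (and optional permutation) inference."""

    I: float
    expected: float
    variance: float
    variance_method: str
    z: float
    p_two_sided: float
    n: int
    p_permutation: Optional[float] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LocalMoranResult:
    """Per-region local Moran's I decomposition with LISA quadrants.

    ``quadrant[i]`` classifies region i by the signs of its deviation
    from the mean and of its spatial lag: HH (high value, high-valued
    neighbors), LL, HL, LH.
    """

    labels: list[str]
    local_i: np.ndarray
    deviation: np.ndarray
    lag: np.ndarray
    quadrant: list[str]
    pseudo_p: np.ndarray

    def __post_init__(self) -> None:
        self.local_i = np.asarray(self.local_i, dtype=float)
        self.deviation = np.asarray(self.deviation, dtype=float)
        self.lag = np.asarray(self.lag, dtype=float)
        self.pseudo_p = np.asarray(self.pseudo_p, dtype=float)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "local_i": self.local_i.tolist(),
            "deviation": self.deviation.tolist(),
            "lag": self.lag.tolist(),
            "quadrant": list(self.quadrant),
            "pseudo_p": self.pseudo_p.tolist(),
        }


@dataclass
class ClassificationResult:
    """Jenks natural-breaks classification of region scores.

    ``breaks`` are the k-1 ascending cut values; a region with value v
    is level 1 (highest) iff v >= breaks[-1], and interior classes are
    left-closed right-open going downward. ``gvf`` is the
    goodness-of-variance-fit, 1 - SSE_within / SSE_total.
    """

    k: int
    breaks: np.ndarray
    labels: np.ndarray
    gvf: float

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "breaks": self.breaks.tolist(),
            "labels": self.labels.tolist(),
            "gvf": self.gvf,
        }


@dataclass(frozen=True)
class ValidationIssue:
    """One violated panel invariant, with cell coordinates when applicable."""

    kind: str
    message: str
    row: Optional[int] = None
    column: Optional[int] = None


def validate_panel(panel: IndicatorPanel) -> list[ValidationIssue]:
    """Check every :class:`IndicatorPanel` invariant; return the violations.

    An empty list means the panel is well formed. This is a reporting
    operation: it never raises for data problems.
    """
    issues: list[ValidationIssue] = []
    m, n = panel.values.shape

    if m < 2:
        issues.append(ValidationIssue("shape", f"need at least 2 regions, got {m}"))
    if n < 1:
        issues.append(ValidationIssue("shape", f"need at least 1 indicator, got {n}"))
    if len(panel.region_labels) != m:
        issues.append(
            ValidationIssue(
                "labels",
                f"{len(panel.region_labels)} region labels for {m} rows",
            )
        )
    if len(panel.scheme) != n:
        issues.append(
            ValidationIssue(
                "scheme", f"scheme has {len(panel.scheme)} entries for {n} columns"
            )
        )
    if panel.missing_mask.shape != panel.values.shape:
        issues.append(ValidationIssue("mask", "missing_mask shape differs from values"))
        return issues  # cell-level checks below would be ill-defined

    seen: set[str] = set()
    for i, label in enumerate(panel.region_labels):
        if label in seen:
            issues.append(
                ValidationIssue("labels", f"duplicate region label {label!r}", row=i)
            )
        seen.add(label)

    seen_codes: set[str] = set()
    for j, d in enumerate(panel.scheme):
        if d.code in seen_codes:
            issues.append(
                ValidationIssue("scheme", f"duplicate indicator code {d.code!r}", column=j)
            )
        seen_codes.add(d.code)

    observed = ~panel.missing_mask
    bad = observed & ~np.isfinite(panel.values)
    for i, j in zip(*np.nonzero(bad)):
        issues.append(
            ValidationIssue(
                "cell",
                "non-finite value outside the missing mask at "
                f"({panel.region_labels[i] if i < len(panel.region_labels) else i}, "
                f"{panel.scheme[j].code if j < len(panel.scheme) else j})",
                row=int(i),
                column=int(j),
            )
        )
    return issues
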