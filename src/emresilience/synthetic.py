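"""Synthetic fixtures: province-like panels, spatial fields, test problems.

Real panels of this kind — a dozen-odd administrative regions described
by a few dozen indicators in four capacity dimensions — are rarely
published, so the generator emulates their structure: 17 regions by 27
indicators laid out 7/8/6/6 across the resistance / restore /
adaptability / collaborative dimensions, three negative-attribute
indicators (population density, disaster count, direct losses),
heterogeneous measurement scales (counts, percentages, 10^4-Yuan
monetary values, mileage), sparse missing cells, and spatially
structured latent quality.

Spatial structure uses a simultaneous-autoregressive (SAR) transform,
x = (I - rho * W)^-1 eps, on row-standardized inverse-distance weights
over random planar coordinates; one rho parameter spans the
negative / null / positive autocorrelation regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import stats

from .core import DIMENSIONS, IndicatorDefinition, IndicatorPanel
from .spatial import build_weights

# (description, units, low, high) per scale family
_FAMILIES = {
    "density": ("population per square km", "people/km^2", 20.0, 1500.0),
    "count_small": ("event or facility count", "count", 0.0, 400.0),
    "count_large": ("personnel or bed count", "count", 100.0, 50000.0),
    "percent": ("coverage rate", "%", 40.0, 100.0),
    "monetary": ("monetary amount", "10^4 Yuan", 1e3, 5e6),
    "capacity": ("shelter capacity", "10^4 people", 0.5, 80.0),
    "mileage": ("route length", "km", 50.0, 30000.0),
}

# code -> (dimension, attribute, family); negative: density, disaster
# count, direct losses (larger raw value = worse status)
_HUBEI_LIKE = {
    "V11": ("resistance", "negative", "density"),
    "V12": ("resistance", "negative", "count_small"),
    "V13": ("resistance", "positive", "count_small"),
    "V14": ("resistance", "negative", "monetary"),
    "V15": ("resistance", "positive", "monetary"),
    "V16": ("resistance", "positive", "capacity"),
    "V17": ("resistance", "positive", "count_small"),
    "V21": ("restore", "positive", "count_large"),
    "V22": ("restore", "positive", "monetary"),
    "V23": ("restore", "positive", "count_large"),
    "V24": ("restore", "positive", "count_large"),
    "V25": ("restore", "positive", "monetary"),
    "V26": ("restore", "positive", "percent"),
    "V27": ("restore", "positive", "count_small"),
    "V28": ("restore", "positive", "monetary"),
    "V31": ("adaptability", "positive", "count_small"),
    "V32": ("adaptability", "positive", "count_small"),
    "V33": ("adaptability", "positive", "count_large"),
    "V34": ("adaptability", "positive", "percent"),
    "V35": ("adaptability", "positive", "monetary"),
    "V36": ("adaptability", "positive", "count_small"),
    "V41": ("collaborative", "positive", "count_large"),
    "V42": ("collaborative", "positive", "percent"),
    "V43": ("collaborative", "positive", "monetary"),
    "V44": ("collaborative", "positive", "count_small"),
    "V45": ("collaborative", "positive", "mileage"),
    "V46": ("collaborative", "positive", "mileage"),
}


def hubei_like_scheme() -> list[IndicatorDefinition]:
    """The default 27-indicator scheme (7/8/6/6 across the dimensions)."""
    scheme = []
    for code, (dim, attr, family) in _HUBEI_LIKE.items():
        desc, units, _, _ = _FAMILIES[family]
        scheme.append(IndicatorDefinition(code, dim, attr, desc, units))
    return scheme


def _generic_scheme(n_indicators: int) -> list[IndicatorDefinition]:
    """Round-robin scheme for non-default indicator counts."""
    fams = list(_FAMILIES)
    scheme = []
    for j in range(n_indicators):
        dim = DIMENSIONS[j % len(DIMENSIONS)]
        attr = "negative" if j % 9 == 0 else "positive"
        family = fams[j % len(fams)]
        desc, units, _, _ = _FAMILIES[family]
        scheme.append(IndicatorDefinition(f"S{j+1:02d}", dim, attr, desc, units))
    return scheme


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings.

    ``latent_dimension_strength`` scales how strongly indicators load
    on their dimension's latent quality factor relative to unit
    idiosyncratic noise (0 gives uncorrelated indicators);
    ``spatial_rho`` is the SAR coefficient of the latent factors;
    ``missing_rate`` defaults to 0.013 — about six missing cells on the
    17 x 27 layout, the sparsity the emulated data situation presents.
    """

    n_regions: int = 17
    n_indicators: int = 27
    latent_dimension_strength: float = 1.0
    spatial_rho: float = 0.4
    missing_rate: float = 0.013
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_indicators < len(DIMENSIONS):
            raise ValueError("need at least one indicator per dimension")
        if not -1.0 < self.spatial_rho < 1.0:
            raise ValueError("spatial_rho must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must lie in [0, 0.1]")
        if self.latent_dimension_strength < 0:
            raise ValueError("latent_dimension_strength must be nonnegative")

    def scheme(self) -> list[IndicatorDefinition]:
        if self.n_indicators == 27:
            return hubei_like_scheme()
        return _generic_scheme(self.n_indicators)


def make_spatial_field(
    coords: np.ndarray,
    rho: float,
    seed: Union[int, np.random.Generator] = 0,
    weights=None,
) -> np.ndarray:
    """SAR field x = (I - rho W)^-1 eps on row-standardized weights.

    ``rho = 0`` gives an i.i.d. standard Gaussian field; positive rho
    smooth, spatially clustered values; negative rho checkerboard-like
    dissimilarity. By default W is inverse-distance with the
    minimum-coverage cutoff (keeping the structure local); pass a
    :class:`~emresilience.core.SpatialWeights` to override.
    """
    coords = np.asarray(coords, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = coords.shape[0]
    if weights is None:
        W = build_weights(coords, row_standardize=True).matrix
    else:
        W = weights.row_standardized().matrix if not weights.standardized else weights.matrix
    eps = rng.standard_normal(n)
    A = np.eye(n) - rho * W
    if abs(np.linalg.det(A)) < 1e-12:
        raise np.linalg.LinAlgError("SAR transform singular at this rho")
    return np.linalg.solve(A, eps)


def make_panel(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> tuple[IndicatorPanel, np.ndarray]:
    """Generate a study-shaped panel and region coordinates.

    Latent per-region quality factors (one per dimension) are SAR
    fields; each indicator is loading * factor + noise mapped through
    the Gaussian CDF onto its scale family's range, with the sign
    flipped for negative-attribute indicators so larger raw values mean
    worse status. Missing cells (at most one per column) are masked at
    ``missing_rate``. Deterministic: same spec and seed give
    byte-identical output.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    m = spec.n_regions
    scheme = spec.scheme()
    n = len(scheme)

    coords = rng.uniform(0.0, 100.0, size=(m, 2))
    factors = {
        dim: make_spatial_field(coords, spec.spatial_rho, rng) for dim in DIMENSIONS
    }

    values = np.empty((m, n))
    for j, d in enumerate(scheme):
        fam = _HUBEI_LIKE[d.code][2] if d.code in _HUBEI_LIKE else _FAMILIES_for(d)
        _, _, lo, hi = _FAMILIES[fam]
        loading = rng.uniform(0.6, 1.0) * spec.latent_dimension_strength
        latent = loading * factors[d.dimension] + rng.standard_normal(m)
        # standardize the latent mix so the CDF mapping stays well spread
        latent = latent / np.sqrt(loading**2 + 1.0)
        if d.attribute == "negative":
            latent = -latent
        values[:, j] = lo + (hi - lo) * stats.norm.cdf(latent)

    mask = np.zeros((m, n), dtype=bool)
    n_missing = int(round(spec.missing_rate * m * n))
    n_missing = min(n_missing, n)  # at most one per column
    if n_missing > 0:
        cols = rng.choice(n, size=n_missing, replace=False)
        rows = rng.integers(0, m, size=n_missing)
        mask[rows, cols] = True
        values = values.copy()
        values[mask] = np.nan

    labels = [f"Region{i+1:02d}" for i in range(m)]
    panel = IndicatorPanel(labels, scheme, values, mask)
    return panel, coords


def _FAMILIES_for(d: IndicatorDefinition) -> str:
    # generic-scheme indicators carry their family via the description
    for fam, (desc, units, _, _) in _FAMILIES.items():
        if d.description == desc and d.units == units:
            return fam
    return "count_small"


@dataclass
class KnownOptimumProblem:
    """A test problem with an analytically known answer.

    Exactly one of ``objective`` (with ``bounds`` and ``argmax``) or
    ``panel`` (with ``planted_index``) is populated, depending on the
    problem kind. ``certificate`` states why the answer is correct.
    """

    kind: str
    certificate: str
    objective: Optional[Callable[[np.ndarray], float]] = None
    bounds: Optional[np.ndarray] = None
    argmax: Optional[np.ndarray] = None
    panel: Optional[IndicatorPanel] = None
    planted_index: Optional[int] = None


def make_known_optimum_problem(kind: str, seed: int = 0) -> KnownOptimumProblem:
    """Construct a certified optimizer or weighting test problem.

    ``quadratic_1d``: f(x) = -(x - 0.3)^2 on [0, 1], argmax 0.3.
    ``sphere_nd``: f(x) = -sum (x_j - c_j)^2 with c = (0.1, 0.5, 0.9).
    ``dominant_indicator_panel``: a panel where one planted indicator
    splits the regions into two well-separated groups while every other
    indicator is unstructured mid-scale noise; the planted indicator is
    the most projection-worthy one (maximal univariate spread * density).
    """
    if kind == "quadratic_1d":
        c = 0.3
        return KnownOptimumProblem(
            kind=kind,
            certificate="unique maximum of a concave parabola at x = 0.3",
            objective=lambda x: -float((x[0] - c) ** 2),
            bounds=np.array([[0.0, 1.0]]),
            argmax=np.array([c]),
        )
    if kind == "sphere_nd":
        c = np.array([0.1, 0.5, 0.9])
        return KnownOptimumProblem(
            kind=kind,
            certificate="unique maximum of the negated sphere at its center",
            objective=lambda x: -float(((x - c) ** 2).sum()),
            bounds=np.tile([0.0, 1.0], (3, 1)),
            argmax=c,
        )
    if kind == "dominant_indicator_panel":
        rng = np.random.default_rng(seed)
        m, n = 17, 10
        planted = 3
        # the non-planted indicators are noisy copies of one shared
        # regional pattern, so in the indicator-as-observation view they
        # project onto (nearly) the same point under any direction; only
        # the planted indicator, independent and bimodal, can be
        # separated from that cluster
        base = rng.uniform(40.0, 60.0, size=m)
        values = base[:, None] + rng.normal(0.0, 0.3, size=(m, n))
        group = rng.permutation(m) < m // 2
        values[:, planted] = np.where(group, 95.0, 5.0) + rng.normal(0, 1.0, m)
        scheme = [
            IndicatorDefinition(
                f"P{j+1:02d}", DIMENSIONS[j % 4], "positive", "synthetic indicator"
            )
            for j in range(n)
        ]
        panel = IndicatorPanel([f"Region{i+1:02d}" for i in range(m)], scheme, values)
        return KnownOptimumProblem(
            kind=kind,
            certificate=(
                "all non-planted indicators are noisy copies of one shared "
                "regional pattern and project to nearly one point under any "
                "direction; the planted indicator is independent and bimodal, "
                "so separating it is the only way to gain spread, and it is "
                "the extreme projection value at the optimum"
            ),
            panel=panel,
            planted_index=planted,
        )
    raise ValueError(f"unknown problem kind {kind!r}")
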