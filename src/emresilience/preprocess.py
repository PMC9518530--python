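"""Missing-value imputation and attribute-oriented min-max standardization.

Standardization maps every indicator onto [0, 1] so that larger always
means better: positive indicators via (x - min) / (max - min), negative
indicators (where larger raw values mean worse status) via
(max - x) / (max - min). This removes both unit heterogeneity and
orientation before projection pursuit.

Imputation fills sparse missing cells with a noisy predictive draw:
an ordinary-least-squares prediction of the incomplete column from the
fully observed columns, plus Gaussian noise scaled to the residual
spread, generating several candidates of which one is kept by a fixed
selection rule. The procedure is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateColumnError,
    IncompletePanelError,
    IndicatorPanel,
    InsufficientDataError,
    StandardizedPanel,
)


@dataclass
class ImputationConfig:
    """Settings of the noisy-candidate imputation procedure.

    ``noise_scale`` multiplies the regression residual standard
    deviation; with ``noise_scale -> 0`` the imputed value converges to
    the deterministic regression prediction. ``selection_rule`` is
    ``closest_to_mean`` (keep the candidate nearest the candidate mean)
    or ``pooled_mean`` (keep the mean of the candidates).
    """

    n_candidates: int = 5
    noise_scale: float = 1.0
    selection_rule: str = "closest_to_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.selection_rule not in ("closest_to_mean", "pooled_mean"):
            raise ValueError(
                "selection_rule must be 'closest_to_mean' or 'pooled_mean'"
            )


def standardize(
    panel: IndicatorPanel, *, drop_degenerate: bool = False
) -> StandardizedPanel:
    """Min-max standardize a complete panel with attribute orientation.

    Parameters
    ----------
    panel
        Complete panel (no missing cells).
    drop_degenerate
        If True, constant columns are dropped with a warning instead of
        raising :class:`DegenerateColumnError`.
    """
    if not panel.is_complete:
        n_miss = int(panel.missing_mask.sum())
        raise IncompletePanelError(
            f"panel has {n_miss} missing cell(s); impute before standardizing"
        )

    X = panel.values
    col_min = X.min(axis=0)
    col_max = X.max(axis=0)
    span = col_max - col_min

    degenerate = [j for j in range(X.shape[1]) if span[j] == 0]
    keep = list(range(X.shape[1]))
    if degenerate:
        codes = [panel.scheme[j].code for j in degenerate]
        if not drop_degenerate:
            raise DegenerateColumnError(
                f"constant column(s) cannot be standardized: {', '.join(codes)}"
            )
        warnings.warn(
            f"dropping degenerate (constant) column(s): {', '.join(codes)}",
            stacklevel=2,
        )
        keep = [j for j in keep if j not in set(degenerate)]
        if not keep:
            raise DegenerateColumnError("all columns are constant")

    out = np.empty((X.shape[0], len(keep)))
    for pos, j in enumerate(keep):
        col = (X[:, j] - col_min[j]) / span[j]
        if panel.scheme[j].attribute == "negative":
            col = 1.0 - col
        out[:, pos] = col

    return StandardizedPanel(
        region_labels=list(panel.region_labels),
        scheme=[panel.scheme[j] for j in keep],
        values=out,
        col_min=col_min[keep],
        col_max=col_max[keep],
    )


def _fit_predict_column(
    X: np.ndarray,
    target: int,
    predictors: list[int],
    observed_rows: np.ndarray,
    missing_rows: np.ndarray,
) -> tuple[np.ndarray, float]:
    """OLS prediction of a column from complete columns.

    Returns predictions at the missing rows and the residual standard
    deviation. Falls back to an intercept-only (column mean) model when
    no predictors are available or the design is rank-deficient beyond
    use.
    """
    y = X[observed_rows, target]
    n_obs = y.size

    if predictors and n_obs > len(predictors) + 1:
        A = np.column_stack([np.ones(n_obs), X[np.ix_(observed_rows, predictors)]])
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ beta
        dof = max(n_obs - rank, 1)
        resid_sd = float(np.sqrt(np.sum((y - fitted) ** 2) / dof))
        A_miss = np.column_stack(
            [np.ones(missing_rows.sum()), X[np.ix_(missing_rows, predictors)]]
        )
        pred = A_miss @ beta
    else:
        pred = np.full(int(missing_rows.sum()), y.mean())
        resid_sd = float(y.std(ddof=1)) if n_obs > 1 else 0.0
    return pred, resid_sd


def impute(panel: IndicatorPanel, cfg: ImputationConfig) -> IndicatorPanel:
    """Fill missing cells with noisy regression-based predictive draws.

    Observed cells are never modified. For each missing cell the
    prediction from the fully observed columns is perturbed with
    Gaussian noise of scale ``noise_scale * residual_sd``,
    ``n_candidates`` candidates are formed, and one value is kept per
    ``selection_rule``.
    """
    if panel.is_complete:
        return panel.copy()

    mask = panel.missing_mask
    m, n = panel.values.shape

    obs_per_col = (~mask).sum(axis=0)
    short = [panel.scheme[j].code for j in range(n) if obs_per_col[j] < 3]
    if short:
        raise InsufficientDataError(
            f"column(s) with fewer than 3 observed values: {', '.join(short)}"
        )
    if (mask.all(axis=1)).any():
        i = int(np.nonzero(mask.all(axis=1))[0][0])
        raise InsufficientDataError(
            f"region {panel.region_labels[i]!r} has no observed values"
        )

    rng = np.random.default_rng(cfg.seed)
    out = panel.copy()
    X = out.values
    complete_cols = [j for j in range(n) if not mask[:, j].any()]

    for j in range(n):
        col_mask = mask[:, j]
        if not col_mask.any():
            continue
        predictors = [c for c in complete_cols if c != j]
        observed_rows = ~col_mask
        pred, resid_sd = _fit_predict_column(X, j, predictors, observed_rows, col_mask)
        rows = np.nonzero(col_mask)[0]
        for pos, i in enumerate(rows):
            noise = rng.standard_normal(cfg.n_candidates)
            candidates = pred[pos] + cfg.noise_scale * resid_sd * noise
            if cfg.selection_rule == "pooled_mean":
                value = float(candidates.mean())
            else:  # closest_to_mean
                center = candidates.mean()
                value = float(candidates[np.argmin(np.abs(candidates - center))])
            X[i, j] = value
            out.missing_mask[i, j] = False

    return out
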