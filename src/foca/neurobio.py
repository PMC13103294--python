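"""Neurobiological-axis prediction of the FOCA matrix.

Per-network values of cortical axes (anatomical hierarchy, evolutionary
expansion, allometric scaling, aerobic glycolysis, cerebral blood flow, gene
expression PC1, meta-analytic decoding PC1, externopyramidization, cortical
thickness) are turned into network-pair alignment matrices (1 minus pairwise
difference after min-max scaling).  The alignment matrices jointly predict the
FOCA matrix edges in a multiple linear regression evaluated by repeated
10-fold cross-validation with adjusted R-squared, a permutation p-value, and
standardized feature weights decomposed into percentage contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.model_selection import KFold

from .topography import FocaMatrix, upper_triangle

__all__ = [
    "AXIS_NAMES",
    "RegressionResult",
    "alignment_matrix",
    "fit_axes_regression",
    "feature_contributions",
]

AXIS_NAMES = [
    "anatomical_hierarchy",
    "evolutionary_expansion",
    "allometric_scaling",
    "aerobic_glycolysis",
    "cerebral_blood_flow",
    "gene_expression_pc1",
    "neurosynth_pc1",
    "externopyramidization",
    "cortical_thickness",
]


@dataclass
class RegressionResult:
    adjusted_r2: float
    fold_r2: np.ndarray  # per-repeat pooled out-of-fold adjusted R^2
    perm_p: float
    weights: dict[str, float]  # standardized coefficients, full-data fit
    raw_weights: dict[str, float] = field(default_factory=dict)  # original scale
    contributions: dict[str, float] = field(default_factory=dict)  # percentages
    n_edges: int = 0


def alignment_matrix(axis_values: np.ndarray) -> np.ndarray:
    """Network-pair alignment of one axis: 1 - |v_i - v_j| after min-max
    scaling to [0, 1].  Symmetric with unit diagonal."""
    v = np.asarray(axis_values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("axis_values must be a length-K vector, K >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("axis values must be finite")
    rng = v.max() - v.min()
    if rng < 1e-12:
        raise ValueError("constant axis: alignment undefined (zero range)")
    s = (v - v.min()) / rng
    a = 1.0 - np.abs(s[:, None] - s[None, :])
    np.fill_diagonal(a, 1.0)
    return a


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_predictors: int) -> float:
    n = len(y)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def _cv_adjusted_r2(
    x: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> float:
    """Pooled out-of-fold predictions -> adjusted R^2 for one fold split."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    yhat = np.empty_like(y)
    xi = np.column_stack([np.ones(len(y)), x])
    for tr, te in kf.split(x):
        beta, *_ = np.linalg.lstsq(xi[tr], y[tr], rcond=None)
        yhat[te] = xi[te] @ beta
    return _adjusted_r2(y, yhat, x.shape[1])


def fit_axes_regression(
    foca: FocaMatrix,
    alignment_set: dict[str, np.ndarray],
    n_folds: int = 10,
    n_repeats: int = 100,
    n_perms: int = 10000,
    seed: int = 0,
) -> RegressionResult:
    """Cross-validated multiple regression of FOCA edges on axis alignments.

    Observations are the strict upper-triangle network pairs; per repeat the
    out-of-fold predictions are pooled into an adjusted R-squared.  The
    permutation p-value shuffles the edge targets.  Standardized coefficients
    come from the full-data fit on z-scored features and target.
    """
    if len(alignment_set) < 2:
        raise ValueError("need at least two alignment features")
    names = list(alignment_set)
    y = upper_triangle(foca.values)
    x = np.column_stack([upper_triangle(alignment_set[n]) for n in names])
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("more predictors than informative edges")
    cond = np.linalg.cond(np.column_stack([np.ones(n), x]))
    if cond > 1e8:
        warnings.warn(f"collinear alignment features (condition number {cond:.2e})")
    rng = np.random.default_rng(seed)
    fold_r2 = np.array([_cv_adjusted_r2(x, y, n_folds, rng) for _ in range(n_repeats)])
    obs = float(fold_r2.mean())
    # permutation null: one CV evaluation per shuffled target
    perm_stats = np.empty(n_perms)
    for b in range(n_perms):
        perm_stats[b] = _cv_adjusted_r2(x, rng.permutation(y), n_folds, rng)
    perm_p = float((1 + np.sum(perm_stats >= obs)) / (n_perms + 1))
    # standardized full-data coefficients
    xs = (x - x.mean(0)) / x.std(0, ddof=0)
    ys = (y - y.mean()) / y.std(ddof=0)
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), xs]), ys, rcond=None)
    weights = {nm: float(b) for nm, b in zip(names, beta[1:])}
    raw_beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)
    raw_weights = {nm: float(b) for nm, b in zip(names, raw_beta[1:])}
    res = RegressionResult(
        adjusted_r2=obs,
        fold_r2=fold_r2,
        perm_p=perm_p,
        weights=weights,
        raw_weights=raw_weights,
        n_edges=n,
    )
    res.contributions = feature_contributions(weights)
    return res


def feature_contributions(weights: dict[str, float]) -> dict[str, float]:
    """Percentage contribution of each feature: |beta_i| / sum_j |beta_j| * 100."""
    vals = np.array([abs(w) for w in weights.values()], dtype=float)
    if len(vals) == 0 or not np.any(np.isfinite(vals)) or vals.sum() == 0:
        raise ValueError("contributions undefined for all-zero weights")
    pct = vals / vals.sum() * 100.0
    return {n: float(p) for n, p in zip(weights, pct)}
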