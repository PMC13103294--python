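"""Developmental modelling and prediction on FOCA couplings.

Mass-univariate edge-wise smooth-age models (penalized cubic B-splines with
GCV-selected smoothing, linear covariates) map developmental refinement of the
coupling matrix; two-group contrasts give Cohen's d effect maps; per-network
multiple regressions relate couplings at birth to later behavioural scores;
and linear support-vector regression predicts chronological age from
vectorized coupling features with train-fold confound removal.

Edge-wise smooth-term p-values come from the exact F-test of the unpenalized
spline block (covariates-only vs covariates + age spline); fitted trajectories
come from the penalized fit.  Under a Gaussian null the F-test p-values are
exactly uniform, which keeps Benjamini–Hochberg error control calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .synthgen import SubjectMeta
from .topography import FocaMatrix, upper_triangle

__all__ = [
    "EdgeModelTable",
    "EffectTable",
    "PredictionReport",
    "spline_basis",
    "fit_edge_trajectories",
    "group_difference",
    "predict_behaviour",
    "predict_age_svr",
    "compare_prediction",
]


@dataclass
class EdgeModelTable:
    """Edge-wise smooth-age model results."""

    table: pd.DataFrame  # per edge: i, j, f_stat, p, q, edf
    trajectories: np.ndarray  # (n_edges, len(age_grid)) penalized fits
    age_grid: np.ndarray
    family_size: int  # number of edges in the BH family


@dataclass
class EffectTable:
    """Two-group contrast per edge."""

    t: np.ndarray  # K x K
    d: np.ndarray  # K x K Cohen's d
    p: np.ndarray
    q: np.ndarray


@dataclass
class PredictionReport:
    accuracy_r: float
    per_repeat_r: np.ndarray
    perm_p: float | None = None
    table: pd.DataFrame | None = None  # per-network behaviour results
    family_size: int | None = None


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def _covariate_design(meta_list: list[SubjectMeta], include_age: bool = False) -> np.ndarray:
    sex = np.array([1.0 if m.sex == "M" else 0.0 for m in meta_list])
    fd = np.array([m.mean_fd for m in meta_list])
    sbi = np.array([m.scan_birth_interval for m in meta_list])
    cols = [np.ones(len(meta_list)), sex, fd, sbi]
    if include_age:
        cols.append(np.array([m.age for m in meta_list]))
    x = np.column_stack(cols)
    keep = [0] + [j for j in range(1, x.shape[1]) if x[:, j].std() > 1e-12]
    return x[:, keep]


def spline_basis(age: np.ndarray, grid: np.ndarray | None = None, k: int = 5):
    """Cubic B-spline basis with ``k`` functions over the age range.

    Returns (basis at ``age``, basis at ``grid`` or None, second-difference
    penalty matrix).  The penalty nullspace contains linear functions, so
    heavy smoothing shrinks the fit to a straight line.
    """
    lo, hi = float(age.min()), float(age.max())
    n_interior = k - 4  # cubic: k = n_interior + 4
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior > 0 else []
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    def design(a):
        a = np.clip(a, lo, hi)
        cols = [BSpline.basis_element(knots[i : i + 5], extrapolate=False)(a)
                for i in range(k)]
        b = np.nan_to_num(np.column_stack(cols), nan=0.0)
        return b
    b_age = design(age)
    b_grid = design(grid) if grid is not None else None
    d = np.diff(np.eye(k), n=2, axis=0)
    return b_age, b_grid, d.T @ d


def _penalized_fit(
    x0: np.ndarray, b: np.ndarray, pen: np.ndarray, y: np.ndarray,
    lambdas: np.ndarray | None = None,
):
    """GCV-selected ridge fit of [covariates | spline] for many targets at once.

    ``y`` is (n, m): the same design is shared across m edges; the smoothing
    parameter is selected per edge by generalized cross-validation.
    """
    if lambdas is None:
        lambdas = np.logspace(-4, 8, 25)
    x = np.column_stack([x0, b])
    n, p0 = x0.shape
    k = b.shape[1]
    pen_full = np.zeros((p0 + k, p0 + k))
    pen_full[p0:, p0:] = pen
    xtx = x.T @ x
    xty = x.T @ y
    best_gcv = np.full(y.shape[1], np.inf)
    best_beta = np.zeros((p0 + k, y.shape[1]))
    best_edf = np.zeros(y.shape[1])
    for lam in lambdas:
        a = xtx + lam * pen_full
        try:
            ainv = np.linalg.inv(a)
        except np.linalg.LinAlgError:
            continue
        beta = ainv @ xty
        yhat = x @ beta
        edf = float(np.trace(x @ ainv @ x.T))
        rss = ((y - yhat) ** 2).sum(axis=0)
        gcv = n * rss / (n - edf) ** 2
        better = gcv < best_gcv
        best_gcv = np.where(better, gcv, best_gcv)
        best_beta[:, better] = beta[:, better]
        best_edf = np.where(better, edf, best_edf)
    return best_beta, best_edf


def fit_edge_trajectories(
    foca_list: list[FocaMatrix],
    meta_list: list[SubjectMeta],
    age_grid: np.ndarray | None = None,
    fdr_q: float = 0.05,
    basis_k: int = 5,
) -> EdgeModelTable:
    """Edge-wise smooth-age models with sex / mean-FD / scan–birth covariates.

    Each edge's coupling across subjects is modelled as covariates plus a
    smooth function of age.  Smooth-term significance is the F-test of the
    spline block; Benjamini–Hochberg FDR runs across all edges; fitted
    trajectories (covariates at their means) are evaluated on ``age_grid``.
    """
    if len(foca_list) < 30:
        raise ValueError("need at least 30 subjects")
    ages = np.array([m.age for m in meta_list])
    if ages.max() - ages.min() < 3:
        raise ValueError("ages must span at least 3 units")
    if age_grid is None:
        age_grid = np.linspace(ages.min(), ages.max(), 25)
    k = foca_list[0].k
    y = np.column_stack([upper_triangle(f.values) for f in foca_list]).T  # (n, E)
    n, n_edges = y.shape
    x0 = _covariate_design(meta_list)
    b_age, b_grid, pen = spline_basis(ages, age_grid, k=basis_k)
    # exact unpenalized block F-test: covariates-only vs covariates + spline
    x_full = np.column_stack([x0, b_age])
    q_full = np.linalg.matrix_rank(x_full)
    q_red = np.linalg.matrix_rank(x0)
    h0_hat = x0 @ np.linalg.lstsq(x0, y, rcond=None)[0]
    h1_hat = x_full @ np.linalg.lstsq(x_full, y, rcond=None)[0]
    rss0 = ((y - h0_hat) ** 2).sum(axis=0)
    rss1 = ((y - h1_hat) ** 2).sum(axis=0)
    df1 = q_full - q_red
    df2 = n - q_full
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = stats.f.sf(f, df1, df2)
    _, q, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    # penalized trajectories
    beta, edf = _penalized_fit(x0, b_age, pen, y)
    cov_means = x0.mean(axis=0)
    grid_design = np.column_stack([np.tile(cov_means, (len(age_grid), 1)), b_grid])
    traj = (grid_design @ beta).T
    iu = np.triu_indices(k, 1)
    table = pd.DataFrame(
        {
            "network_i": iu[0] + 1,
            "network_j": iu[1] + 1,
            "f_stat": f,
            "p": p,
            "q": q,
            "edf": edf,
        }
    )
    return EdgeModelTable(
        table=table, trajectories=traj, age_grid=age_grid, family_size=n_edges
    )


# ---------------------------------------------------------------------------
# group contrast
# ---------------------------------------------------------------------------


def group_difference(
    foca_group_a: list[FocaMatrix], foca_group_b: list[FocaMatrix]
) -> EffectTable:
    """Two-sample t and pooled-SD Cohen's d per edge (A minus B)."""
    if len(foca_group_a) < 2 or len(foca_group_b) < 2:
        raise ValueError("need at least two subjects per group")
    a = np.stack([f.values for f in foca_group_a])
    b = np.stack([f.values for f in foca_group_b])
    na, nb = len(a), len(b)
    ma, mb = a.mean(0), b.mean(0)
    va, vb = a.var(0, ddof=1), b.var(0, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if np.any(pooled[~np.eye(pooled.shape[0], dtype=bool)] < 1e-15):
        raise ValueError("zero pooled variance on some edge")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (ma - mb) / pooled
        t = d / np.sqrt(1.0 / na + 1.0 / nb)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), na + nb - 2)
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(p.shape[0], 1)
    _, q_flat, _, _ = multipletests(p[iu], method="fdr_bh")
    q = np.ones_like(p)
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    return EffectTable(t=t, d=d, p=p, q=q)


# ---------------------------------------------------------------------------
# behaviour prediction
# ---------------------------------------------------------------------------


def predict_behaviour(
    foca_list: list[FocaMatrix],
    meta_list: list[SubjectMeta],
    score_name: str,
    fdr_q: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
) -> PredictionReport:
    """Per-network prediction of a behavioural score from coupling profiles.

    One multiple regression per network: the score on covariates (sex, mean
    FD, scan age, scan–birth interval) plus the network's K-1 couplings.
    Significance is the partial F of the coupling block after covariates, with
    BH-FDR across the K networks; a 10-fold cross-validated accuracy r is
    reported per network as a descriptive.
    """
    scores = np.array([m.behaviour_scores.get(score_name, np.nan) for m in meta_list])
    ok = np.isfinite(scores)
    if ok.sum() < 30:
        raise ValueError("scores present for fewer than 30 subjects")
    metas = [m for m, o in zip(meta_list, ok) if o]
    focas = [f for f, o in zip(foca_list, ok) if o]
    y = scores[ok]
    k = focas[0].k
    x_cov = _covariate_design(metas, include_age=True)
    n = len(y)
    if n <= x_cov.shape[1] + k - 1:
        raise ValueError("more predictors than subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for net in range(k):
        prof = np.stack([np.delete(f.values[net], net) for f in focas])  # (n, K-1)
        x_full = np.column_stack([x_cov, prof])
        rss0 = _rss(x_cov, y)
        rss1 = _rss(x_full, y)
        df1 = prof.shape[1]
        df2 = n - x_full.shape[1]
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
        p = stats.f.sf(f, df1, df2)
        r_cv = _cv_accuracy(x_full, y, n_folds, rng)
        r_in = float(np.corrcoef(_fitted(x_full, y), y)[0, 1])
        rows.append({"network": net + 1, "f_stat": f, "p": p,
                     "cv_r": r_cv, "in_sample_r": r_in})
    tab = pd.DataFrame(rows)
    _, tab["q"], _, _ = multipletests(tab["p"], alpha=fdr_q, method="fdr_bh")
    return PredictionReport(
        accuracy_r=float(tab["cv_r"].mean()),
        per_repeat_r=tab["cv_r"].to_numpy(),
        table=tab,
        family_size=k,
    )


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(((y - x @ beta) ** 2).sum())


def _fitted(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return x @ beta


def _cv_accuracy(x: np.ndarray, y: np.ndarray, n_folds: int, rng) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    yhat = np.empty_like(y)
    for tr, te in kf.split(x):
        beta, *_ = np.linalg.lstsq(x[tr], y[tr], rcond=None)
        yhat[te] = x[te] @ beta
    return float(np.corrcoef(yhat, y)[0, 1])


# ---------------------------------------------------------------------------
# age prediction (linear SVR)
# ---------------------------------------------------------------------------


def _confound_residualize(train_x, test_x, train_c, test_c):
    """Fit confound regression on the training fold, apply to both folds."""
    ci_tr = np.column_stack([np.ones(len(train_c)), train_c])
    ci_te = np.column_stack([np.ones(len(test_c)), test_c])
    beta, *_ = np.linalg.lstsq(ci_tr, train_x, rcond=None)
    return train_x - ci_tr @ beta, test_x - ci_te @ beta


def predict_age_svr(
    feature_matrices: np.ndarray,
    meta_list: list[SubjectMeta],
    n_folds: int = 10,
    n_repeats: int = 100,
    n_perms: int = 0,
    seed: int = 0,
    edge_mask: np.ndarray | None = None,
) -> PredictionReport:
    """Linear SVR prediction of chronological age from coupling features.

    ``feature_matrices`` is (n_subjects, n_features) of vectorized edges
    (optionally restricted via ``edge_mask``).  Confounds (sex, mean FD,
    scan–birth interval) are regressed from features and ages using
    train-fold-fitted coefficients only.  Accuracy is the Pearson r between
    held-out predictions and (residualized) ages, pooled per repeat.
    """
    x_all = np.asarray(feature_matrices, dtype=float)
    if edge_mask is not None:
        x_all = x_all[:, edge_mask]
    ages = np.array([m.age for m in meta_list])
    conf = _covariate_design(meta_list)[:, 1:]  # drop intercept column
    n = len(ages)
    if n_folds > n:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)

    def one_run(y: np.ndarray, rs: int) -> float:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
        yhat = np.empty(n)
        yres = np.empty(n)
        for tr, te in kf.split(x_all):
            xt, xe = _confound_residualize(x_all[tr], x_all[te], conf[tr], conf[te])
            yt, ye = _confound_residualize(
                y[tr, None], y[te, None], conf[tr], conf[te]
            )
            model = SVR(kernel="linear", C=1.0, epsilon=0.1)
            model.fit(xt, yt.ravel())
            yhat[te] = model.predict(xe)
            yres[te] = ye.ravel()
        return float(np.corrcoef(yhat, yres)[0, 1])

    per_rep = np.array(
        [one_run(ages, int(rng.integers(2**31 - 1))) for _ in range(n_repeats)]
    )
    obs = float(per_rep.mean())
    perm_p = None
    if n_perms > 0:
        null = np.array(
            [
                one_run(rng.permutation(ages), int(rng.integers(2**31 - 1)))
                for _ in range(n_perms)
            ]
        )
        perm_p = float((1 + np.sum(null >= obs)) / (n_perms + 1))
    return PredictionReport(accuracy_r=obs, per_repeat_r=per_rep, perm_p=perm_p)


def compare_prediction(report_a: PredictionReport, report_b: PredictionReport) -> dict:
    """Paired t-test over repeats between two feature sets' accuracies."""
    t, p = stats.ttest_rel(report_a.per_repeat_r, report_b.per_repeat_r)
    diff = report_a.per_repeat_r - report_b.per_repeat_r
    d = float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else np.inf
    return {"t": float(t), "p": float(p), "cohens_d": d,
            "mean_a": float(report_a.per_repeat_r.mean()),
            "mean_b": float(report_b.per_repeat_r.mean())}
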