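"""Frozen validation studies exercising the whole package on synthetic data.

Each function sets up one self-contained study — planted couplings, a
simulated cohort, the method under test, and the measured quantity — at a
fixed desk-scale problem size (rectangular 20 x 20 meshes, 5-6 planted
networks for signal-level analyses, the full 20-network / 190-edge layout for
matrix-level analyses).  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats

from . import (
    compare_fc,
    development,
    individualize,
    neurobio,
    preprocess,
    synthgen,
    topography,
)
from .individualize import Parcellation
from .synthgen import EffectSpec, SubjectMeta
from .topography import upper_triangle

__all__ = [
    "normal_tail_percent",
    "smoothing_sigma_mm",
    "block_coupling",
    "oracle_consistency_study",
    "template_recovery_study",
    "axes_recovery_study",
    "gam_null_fdr_study",
    "comparison_battery_study",
    "reliability_study",
]


def normal_tail_percent(z_threshold: float = 1.0) -> float:
    """Percentage of a standard normal above the template z-threshold."""
    return float(100.0 * sp_stats.norm.sf(z_threshold))


def smoothing_sigma_mm(fwhm_mm: float = 6.0) -> float:
    """Gaussian sigma (mm) of the surface-smoothing kernel for a given FWHM."""
    return float(preprocess.fwhm_to_sigma(fwhm_mm))


def block_coupling(k: int, intra: float = 0.5, inter: float = -0.3) -> np.ndarray:
    """Two positive blocks with negative cross-block couplings (PSD-repaired)."""
    c = np.full((k, k), inter)
    half = k // 2
    c[:half, :half] = intra
    c[half:, half:] = intra
    np.fill_diagonal(c, 1.0)
    return synthgen.nearest_psd_correlation(c)


def _parc(labels: np.ndarray, k: int) -> Parcellation:
    return Parcellation(labels=labels, n_networks=k, level="individual")


# ---------------------------------------------------------------------------
# estimator vs closed-form oracle
# ---------------------------------------------------------------------------


def oracle_consistency_study(seed: int = 0, n_frames: int = 5000, k: int = 5) -> dict:
    """Max entrywise deviation of the estimated FOCA matrix from the oracle.

    Zero noise, no global signal, no boundary perturbation: the estimator on
    one long scan should agree with the closed-form expectation entrywise.
    """
    geom = synthgen.make_geometry(20, 20)
    model = synthgen.sample_latent_model(
        k, geom, block_coupling(k),
        EffectSpec(noise_sd=0.0, global_weight=0.0, boundary_shift_rate=0.0),
        seed=seed,
    )
    oracle = synthgen.oracle_foca(model)
    scan = synthgen.simulate_scan(
        model, SubjectMeta(subject_id="oracle"), n_frames=n_frames, seed=seed + 1
    )
    est = topography.compute_foca(
        topography.compute_topography(scan, _parc(model.group_labels, k))
    ).values
    return {"max_abs_dev": float(np.abs(est - oracle).max()), "n_frames": n_frames}


# ---------------------------------------------------------------------------
# template-matching identity recovery
# ---------------------------------------------------------------------------


def template_recovery_study(
    seed: int = 0, k: int = 5, n_template: int = 8, n_test: int = 5
) -> dict:
    """Label agreement of template matching with the planted parcellation.

    Low-noise cohort with unperturbed boundaries: templates are built from one
    subject group, matching is evaluated on held-out subjects against the
    planted labels.
    """
    geom = synthgen.make_geometry(20, 20)
    model = synthgen.sample_latent_model(
        k, geom, block_coupling(k),
        EffectSpec(noise_sd=0.1, global_weight=0.0, boundary_shift_rate=0.0),
        seed=seed,
    )
    cohort = synthgen.simulate_cohort(
        model, n_template + n_test, n_frames=400, seed=seed + 1
    )
    group_parc = Parcellation(labels=model.group_labels, n_networks=k)
    templates = individualize.build_group_templates(cohort[:n_template], group_parc)
    agreements = []
    for scan in cohort[n_template:]:
        parc = individualize.match_templates(scan, templates, geometry=geom)
        agreements.append(float(np.mean(parc.labels == model.group_labels)))
    return {"agreement": float(np.mean(agreements)), "n_subjects": n_test}


# ---------------------------------------------------------------------------
# axis-alignment regression parameter recovery
# ---------------------------------------------------------------------------

_TRUE_W = np.array([0.30, -0.30, 0.25, -0.25, 0.20, -0.20, 0.15, -0.15, 0.10])


def _constructed_foca(seed: int, noise_sd: float):
    """A K=20 coupling matrix built as a linear combination of alignments."""
    rng = np.random.default_rng(seed)
    k = 20
    axes = {name: rng.uniform(0, 1, size=k) for name in neurobio.AXIS_NAMES}
    alignments = {n: neurobio.alignment_matrix(v) for n, v in axes.items()}
    y = sum(w * a for w, a in zip(_TRUE_W, alignments.values()))
    y = y - np.mean(upper_triangle(y))  # centre edges inside [-1, 1]
    if noise_sd > 0:
        e = rng.normal(0, noise_sd, size=(k, k))
        e = (e + e.T) / 2.0
        y = y + e
    y = np.clip(y, -0.99, 0.99)
    np.fill_diagonal(y, 1.0)
    return topography.FocaMatrix(values=(y + y.T) / 2.0), alignments


def axes_recovery_study(seed: int = 0, noise_sd: float = 0.05) -> dict:
    """Weight recovery and out-of-fold adjusted R^2 on constructed targets.

    The noiseless target gives the cross-validated adjusted R^2 ceiling; the
    noisy target (sd on the coupling scale) measures relative weight-recovery
    error of the full-data fit in the original units.
    """
    foca_clean, alignments = _constructed_foca(seed, 0.0)
    clean = neurobio.fit_axes_regression(
        foca_clean, alignments, n_repeats=10, n_perms=200, seed=seed
    )
    foca_noisy, alignments_n = _constructed_foca(seed, noise_sd)
    noisy = neurobio.fit_axes_regression(
        foca_noisy, alignments_n, n_repeats=10, n_perms=200, seed=seed
    )
    w_hat = np.array([noisy.raw_weights[n] for n in neurobio.AXIS_NAMES])
    rel_err = float(np.linalg.norm(w_hat - _TRUE_W) / np.linalg.norm(_TRUE_W))
    return {
        "adjusted_r2_noiseless": float(clean.adjusted_r2),
        "weight_rel_error": rel_err,
        "perm_p_noiseless": clean.perm_p,
        "n_edges": clean.n_edges,
    }


# ---------------------------------------------------------------------------
# GAM error control under the null
# ---------------------------------------------------------------------------


def gam_null_fdr_study(
    seed: int = 0, n_reps: int = 200, n_subjects: int = 60, k: int = 20,
    fdr_q: float = 0.05,
) -> dict:
    """Mean false-discovery proportion of edge screening on null cohorts.

    Couplings are age-independent noise; with Benjamini-Hochberg at level q
    the mean FDP over replicates should sit near q (binomial variation).
    """
    rng = np.random.default_rng(seed)
    fdps = np.empty(n_reps)
    for rep in range(n_reps):
        focas, metas = [], []
        for s in range(n_subjects):
            v = np.clip(rng.normal(0, 0.2, size=(k, k)), -0.99, 0.99)
            v = (v + v.T) / 2.0
            np.fill_diagonal(v, 1.0)
            focas.append(topography.FocaMatrix(values=v, subject_id=f"s{s}"))
            metas.append(
                SubjectMeta(
                    subject_id=f"s{s}",
                    group="neonate",
                    age=float(rng.uniform(37, 44)),
                    sex="F" if rng.random() < 0.5 else "M",
                    mean_fd=float(rng.uniform(0.02, 0.2)),
                    scan_birth_interval=float(rng.uniform(0, 4)),
                )
            )
        table = development.fit_edge_trajectories(focas, metas, fdr_q=fdr_q).table
        n_rej = int((table["q"] < fdr_q).sum())
        fdps[rep] = 1.0 if n_rej > 0 else 0.0  # all rejections are false
    return {
        "mean_fdp": float(fdps.mean()),
        "n_reps": n_reps,
        "q": fdr_q,
    }


# ---------------------------------------------------------------------------
# FOCA vs FC comparison battery
# ---------------------------------------------------------------------------


def _foca_values(scan, k):
    parc = _parc(scan.true_labels, k)
    return topography.compute_foca(topography.compute_topography(scan, parc)).values


def _fc_values(scan, k, gsr=False):
    return compare_fc.conventional_fc(scan, _parc(scan.true_labels, k), gsr=gsr).values


def comparison_battery_study(seed: int = 0) -> dict:
    """The three directional comparisons against conventional FC.

    One cohort with a strong global-signal component and boundary-level
    individual variability drives (a) GSR-toggle normalized RMSE and (b)
    group-to-individual dissimilarity of negative couplings (on GSR data);
    a neonatal cohort with Fisher-z age slopes planted on cross-block
    couplings drives (c) linear-SVR age prediction, run without GSR so the
    global component degrades the temporal-correlation features.
    """
    k = 6
    geom = synthgen.make_geometry(20, 20)
    model = synthgen.sample_latent_model(
        k, geom, block_coupling(k),
        EffectSpec(boundary_shift_rate=0.1, global_weight=1.0, noise_sd=1.0),
        seed=seed,
    )
    scans = synthgen.simulate_cohort(model, 20, n_frames=300, seed=seed + 11)

    nr_foca, nr_fc, f_gsr, c_gsr = [], [], [], []
    for s in scans:
        s_gsr = preprocess.global_signal_regress(s)
        fn, fg = _foca_values(s, k), _foca_values(s_gsr, k)
        cn, cg = _fc_values(s, k), _fc_values(s, k, gsr=True)
        nr_foca.append(compare_fc.gsr_stability(fg, fn))
        nr_fc.append(compare_fc.gsr_stability(cg, cn))
        f_gsr.append(fg)
        c_gsr.append(cg)

    group_f = np.mean(f_gsr, axis=0)
    np.fill_diagonal(group_f, 1.0)
    group_c = np.mean(c_gsr, axis=0)
    dis_f = compare_fc.negative_profile_dissimilarity(group_f, f_gsr)
    dis_c = compare_fc.negative_profile_dissimilarity(group_c, c_gsr)

    age_eff = {(1, 4): 0.04, (2, 5): 0.04, (3, 6): 0.04, (1, 5): -0.04}
    model_dev = synthgen.sample_latent_model(
        k, geom, block_coupling(k),
        EffectSpec(boundary_shift_rate=0.1, global_weight=1.0, noise_sd=1.0,
                   age_effects=age_eff, age_reference=40.5),
        seed=seed,
    )
    neo = synthgen.simulate_cohort(
        model_dev, 50, group="neonate", age_range=(37, 44), n_frames=300,
        seed=seed + 21,
    )
    x_f = np.array([upper_triangle(_foca_values(s, k)) for s in neo])
    x_c = np.array([upper_triangle(_fc_values(s, k)) for s in neo])
    metas = [s.meta for s in neo]
    rep_f = development.predict_age_svr(x_f, metas, n_repeats=20, seed=seed + 5)
    rep_c = development.predict_age_svr(x_c, metas, n_repeats=20, seed=seed + 5)
    paired = development.compare_prediction(rep_f, rep_c)
    return {
        "gsr_nrmse_foca": float(np.mean(nr_foca)),
        "gsr_nrmse_fc": float(np.mean(nr_fc)),
        "dissimilarity_foca": float(np.mean(dis_f)),
        "dissimilarity_fc": float(np.mean(dis_c)),
        "agepred_r_foca": rep_f.accuracy_r,
        "agepred_r_fc": rep_c.accuracy_r,
        "agepred_paired_t": paired["t"],
        "n_subjects_gsr": len(scans),
        "n_subjects_age": len(neo),
    }


# ---------------------------------------------------------------------------
# scan-duration reliability
# ---------------------------------------------------------------------------


def reliability_study(
    seed: int = 0,
    durations_min: tuple[float, ...] = (5.0, 15.0, 30.0),
    n_reps: int = 100,
    noise_sd: float = 20.0,
) -> dict:
    """Mean split-data similarity across sampled scan durations.

    One synthetic 300-minute scan (tr = 2 s); motion-censored frames are
    sampled against a held-out 70-minute reference block.  The default vertex
    noise puts the per-vertex SNR in the low regime typical of surface BOLD,
    so short durations are visibly less reliable than long ones.
    """
    k = 5
    geom = synthgen.make_geometry(20, 20)
    model = synthgen.sample_latent_model(
        k, geom, block_coupling(k),
        EffectSpec(noise_sd=noise_sd, global_weight=0.3, boundary_shift_rate=0.0),
        seed=seed,
    )
    tr = 2.0
    n_frames = int(300 * 60 / tr)
    scan = synthgen.simulate_scan(
        model, SubjectMeta(subject_id="long"), n_frames=n_frames, tr=tr, seed=seed + 1
    )
    scan = preprocess.scrub_frames(scan, 0.5)
    curve = topography.duration_reliability(
        scan, _parc(model.group_labels, k), list(durations_min),
        reference_min=70.0, n_reps=n_reps, seed=seed + 2,
    )
    return {
        "durations_min": list(durations_min),
        "mean_similarity": [float(m) for m in curve["mean"]],
        "n_reps": n_reps,
    }
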