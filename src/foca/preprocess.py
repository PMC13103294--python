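"""Post-acquisition denoising for surface BOLD runs.

Desk-scale analogues of standard resting-state post-processing: multivariate
confound regression, FD-based frame censoring (0.5 mm default), zero-phase
band-pass filtering, geodesic Gaussian surface smoothing, and optional global
signal regression.  All operations take and return :class:`~foca.synthgen.Scan`
objects and append a provenance entry to ``scan.history``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, sparse
from scipy.sparse.csgraph import dijkstra

from .synthgen import Scan, SurfaceGeometry

__all__ = [
    "regress_confounds",
    "scrub_frames",
    "bandpass",
    "smoothing_weights",
    "smooth_surface",
    "smooth_scan",
    "global_signal_regress",
    "fwhm_to_sigma",
]

MIN_SURVIVING_FRAMES = 50


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given full width at half maximum (6 mm -> 2.55 mm)."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of y on the design x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def regress_confounds(scan: Scan, confounds: np.ndarray) -> Scan:
    """Remove nuisance regressors from every vertex series by OLS.

    An intercept column is always included.  Raises if the augmented design is
    rank-deficient, naming the offending columns.
    """
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != scan.n_frames:
        raise ValueError(
            f"confound rows ({c.shape[0]}) != scan frames ({scan.n_frames})"
        )
    x = np.column_stack([np.ones(scan.n_frames), c])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _deficient_columns(x)
        raise ValueError(f"confound design is rank-deficient (columns {bad})")
    resid = _residualize(scan.data, x)
    return scan.copy_with(data=resid, step=f"regress_confounds(p={c.shape[1]})")


def _deficient_columns(x: np.ndarray) -> list[int]:
    bad = []
    for j in range(1, x.shape[1]):
        sub = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
            bad.append(j - 1)  # report in confound indexing (intercept excluded)
    return bad


def scrub_frames(scan: Scan, fd_threshold: float = 0.5) -> Scan:
    """Censor frames whose framewise displacement exceeds the threshold.

    The default 0.5-mm rule mirrors standard motion scrubbing.  Raises if
    fewer than 50 frames survive.
    """
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")
    keep = scan.fd <= fd_threshold
    n_keep = int(keep.sum())
    if n_keep < MIN_SURVIVING_FRAMES:
        raise ValueError(
            f"insufficient data: only {n_keep} frames survive FD <= {fd_threshold}"
        )
    out = Scan(
        data=scan.data[keep],
        tr=scan.tr,
        fd=scan.fd[keep],
        censor_mask=scan.censor_mask[keep],
        meta=scan.meta,
        true_labels=scan.true_labels,
        history=list(scan.history)
        + [f"scrub(thresh={fd_threshold}, kept={n_keep}/{scan.n_frames})"],
    )
    return out


def bandpass(scan: Scan, low_hz: float = 0.01, high_hz: float = 0.08) -> Scan:
    """Zero-phase Butterworth band-pass per vertex; the mean is removed."""
    nyq = 0.5 / scan.tr
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"band [{low_hz}, {high_hz}] must satisfy 0 <= low < high < {nyq}")
    data = scan.data - scan.data.mean(axis=0, keepdims=True)
    if low_hz > 0:
        sos = signal.butter(4, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    else:
        sos = signal.butter(4, high_hz / nyq, btype="low", output="sos")
    filt = signal.sosfiltfilt(sos, data, axis=0)
    filt = filt - filt.mean(axis=0, keepdims=True)
    return scan.copy_with(data=filt, step=f"bandpass({low_hz}-{high_hz}Hz)")


def smoothing_weights(
    geometry: SurfaceGeometry, fwhm_mm: float
) -> sparse.csr_matrix:
    """Row-normalized Gaussian weights over graph-geodesic distances.

    Distances are shortest-path edge lengths on the mesh, truncated at 3 sigma.
    Raises if the mesh is disconnected.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sig = fwhm_to_sigma(fwhm_mm)
    coords = geometry.vertex_coords
    u, v = geometry.edges[:, 0], geometry.edges[:, 1]
    lengths = np.linalg.norm(coords[u] - coords[v], axis=1)
    n = geometry.n_vertices
    g = sparse.coo_matrix((lengths, (u, v)), shape=(n, n))
    g = g + g.T
    dist = dijkstra(g.tocsr(), directed=False, limit=3.0 * sig)
    finite = np.isfinite(dist)
    # connectivity check on the full graph (not the truncated distances)
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(g.tocsr(), directed=False)
    if n_comp > 1:
        raise ValueError("geometry is disconnected; smoothing weights undefined")
    w = np.zeros_like(dist)
    w[finite] = np.exp(-(dist[finite] ** 2) / (2.0 * sig**2))
    w /= w.sum(axis=1, keepdims=True)
    return sparse.csr_matrix(w)


def smooth_surface(
    values: np.ndarray, geometry: SurfaceGeometry, fwhm_mm: float = 6.0
) -> np.ndarray:
    """Smooth a per-vertex map (V,) or a stack of frames (T, V) on the mesh."""
    w = smoothing_weights(geometry, fwhm_mm)
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        return w @ vals
    return (w @ vals.T).T


def smooth_scan(scan: Scan, geometry: SurfaceGeometry, fwhm_mm: float = 6.0) -> Scan:
    """Apply the same surface-smoothing weights to every frame of a scan."""
    smoothed = smooth_surface(scan.data, geometry, fwhm_mm)
    return scan.copy_with(data=smoothed, step=f"smooth(fwhm={fwhm_mm}mm)")


def global_signal_regress(scan: Scan) -> Scan:
    """Regress the cortex-mean time series (with intercept) from every vertex."""
    if scan.n_frames < 2:
        raise ValueError("need at least 2 frames for GSR")
    gs = scan.data.mean(axis=1)
    if np.std(gs) < 1e-12:
        raise ValueError("global signal has zero variance")
    x = np.column_stack([np.ones(scan.n_frames), gs])
    resid = _residualize(scan.data, x)
    return scan.copy_with(data=resid, step="gsr")
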