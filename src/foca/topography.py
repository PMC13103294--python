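"""Functional topography maps and the FOCA matrix.

A network's functional topography is the map of Fisher-z correlations between
its mean (seed) time series and every cortical vertex.  The FOCA (functional
topography covariance) matrix is the K x K matrix of Pearson correlations
between these spatial maps for all network pairs: positive entries are
convergent couplings, negative entries divergent couplings.  This module also
quantifies cross-subject consistency, interindividual variability (median
absolute deviation), and scan-duration reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .individualize import Parcellation
from .synthgen import Scan

__all__ = [
    "TopographySet",
    "FocaMatrix",
    "compute_topography",
    "compute_foca",
    "upper_triangle",
    "matrix_similarity",
    "consistency",
    "variability_mad",
    "duration_reliability",
    "group_mean_foca",
]

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class TopographySet:
    """K per-network Fisher-z seed maps over V vertices."""

    maps: np.ndarray  # (K, V)
    subject_id: str = "group"
    parcellation_level: str = "individual"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("topography maps must be finite")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]


@dataclass(frozen=True)
class FocaMatrix:
    """K x K signed spatial-covariance matrix of topography maps."""

    values: np.ndarray
    subject_id: str = "group"
    network_names: list | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("FOCA matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("FOCA diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("FOCA entries must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return self.values.shape[0]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing arctanh transform with clipping for finiteness."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def compute_topography(
    scan: Scan,
    parcellation: Parcellation,
    nuisance_map: np.ndarray | None = None,
) -> TopographySet:
    """Seed-based Fisher-z topography map for every network.

    The seed series of network i is the mean series over its vertices; the map
    is arctanh(corr(seed_i, x_v)) over all vertices v.  If ``nuisance_map`` is
    given, each map is replaced by its residual after regressing the nuisance
    map out across vertices (with intercept).
    """
    k = parcellation.n_networks
    data = scan.data
    seeds = np.empty((data.shape[0], k))
    for i in range(1, k + 1):
        m = parcellation.mask(i)
        if not m.any():
            raise ValueError(f"network {i} has no vertices")
        seeds[:, i - 1] = data[:, m].mean(axis=1)
    sc = seeds - seeds.mean(axis=0, keepdims=True)
    ss = np.sqrt((sc**2).sum(axis=0))
    if np.any(ss < 1e-12):
        bad = np.where(ss < 1e-12)[0] + 1
        raise ValueError(f"zero-variance seed series for network(s) {list(bad)}")
    dc = data - data.mean(axis=0, keepdims=True)
    ds = np.sqrt((dc**2).sum(axis=0))
    ds = np.where(ds < 1e-12, np.inf, ds)
    r = (sc.T @ dc) / np.outer(ss, ds)
    maps = fisher_z(r)
    if nuisance_map is not None:
        x = np.column_stack([np.ones(maps.shape[1]), np.asarray(nuisance_map, float)])
        beta, *_ = np.linalg.lstsq(x, maps.T, rcond=None)
        maps = (maps.T - x @ beta).T
    return TopographySet(
        maps=maps,
        subject_id=scan.meta.subject_id,
        parcellation_level=parcellation.level,
    )


def compute_foca(topographies: TopographySet) -> FocaMatrix:
    """Pearson-correlate every pair of topography maps across vertices."""
    maps = topographies.maps
    if maps.shape[0] < 2:
        raise ValueError("need at least two networks")
    sd = maps.std(axis=1)
    if np.any(sd < 1e-12):
        bad = np.where(sd < 1e-12)[0] + 1
        raise ValueError(f"constant topography map for network(s) {list(bad)}")
    vals = np.corrcoef(maps)
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return FocaMatrix(values=vals, subject_id=topographies.subject_id)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle (the informative entries)."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def matrix_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between the strict upper triangles of two square matrices."""
    ua, ub = upper_triangle(a), upper_triangle(b)
    return float(np.corrcoef(ua, ub)[0, 1])


def consistency(foca_list: list[FocaMatrix]) -> dict:
    """Cross-subject consistency: pairwise upper-triangle correlations."""
    if len(foca_list) < 2:
        raise ValueError("need at least two matrices")
    ks = {f.k for f in foca_list}
    if len(ks) > 1:
        raise ValueError(f"matrix sizes differ: {sorted(ks)}")
    n = len(foca_list)
    pairs, values = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((foca_list[i].subject_id, foca_list[j].subject_id))
            values.append(matrix_similarity(foca_list[i].values, foca_list[j].values))
    values = np.asarray(values)
    return {
        "pairs": pairs,
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    }


def variability_mad(foca_list: list[FocaMatrix]) -> np.ndarray:
    """Per-edge raw median absolute deviation across subjects.

    MAD = median_s |x_s - median(x)|, a robust dispersion of each coupling.
    """
    if len(foca_list) < 3:
        raise ValueError("need at least three subjects for MAD")
    stack = np.stack([f.values for f in foca_list])
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med[None]), axis=0)
    mad = (mad + mad.T) / 2.0
    np.fill_diagonal(mad, 0.0)
    return mad


def group_mean_foca(foca_list: list[FocaMatrix]) -> FocaMatrix:
    """Element-wise mean FOCA matrix across subjects (diagonal reset to 1)."""
    vals = np.mean([f.values for f in foca_list], axis=0)
    np.fill_diagonal(vals, 1.0)
    return FocaMatrix(values=np.clip(vals, -1, 1), subject_id="group")


def duration_reliability(
    scan: Scan,
    parcellation: Parcellation,
    durations_min: list[float],
    reference_min: float = 70.0,
    n_reps: int = 100,
    seed: int = 0,
    contiguous: bool = True,
) -> dict:
    """Scan-duration reliability of the FOCA matrix.

    A reference FOCA matrix is computed from a fixed held-out block of
    ``reference_min`` minutes at the end of the censored-surviving frames.
    For each duration and repetition, frames are drawn from the remaining pool
    (contiguous runs by default, arbitrary frames otherwise), a FOCA matrix is
    computed, and its upper-triangle correlation with the reference recorded.
    Returns mean and SD per duration plus the raw similarity values.
    """
    rng = np.random.default_rng(seed)
    surv = np.where(scan.censor_mask)[0]
    fps = 60.0 / scan.tr  # frames per minute
    ref_frames = int(round(reference_min * fps))
    if ref_frames >= len(surv):
        raise ValueError("scan too short for the requested reference duration")
    ref_idx = surv[-ref_frames:]
    pool = surv[:-ref_frames]
    max_frames = int(round(max(durations_min) * fps))
    if max_frames > len(pool):
        raise ValueError("insufficient frames for the longest requested duration")
    ref_scan = scan.copy_with(data=scan.data[ref_idx], fd=scan.fd[ref_idx],
                              censor_mask=scan.censor_mask[ref_idx])
    ref = compute_foca(compute_topography(ref_scan, parcellation)).values
    means, sds, raw = [], [], {}
    for d in durations_min:
        n_frames = int(round(d * fps))
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            if contiguous:
                start = rng.integers(0, len(pool) - n_frames + 1)
                idx = pool[start : start + n_frames]
            else:
                idx = rng.choice(pool, size=n_frames, replace=False)
            sub = scan.copy_with(data=scan.data[idx], fd=scan.fd[idx],
                                 censor_mask=scan.censor_mask[idx])
            f = compute_foca(compute_topography(sub, parcellation)).values
            vals[rep] = matrix_similarity(f, ref)
        raw[d] = vals
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if n_reps > 1 else 0.0)
    return {
        "durations_min": list(durations_min),
        "mean": np.asarray(means),
        "sd": np.asarray(sds),
        "values": raw,
        "reference_min": reference_min,
    }
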