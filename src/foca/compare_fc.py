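"""Conventional FC and the FOCA-versus-FC comparison battery.

Conventional functional connectivity (FC) here is the Fisher-z temporal
correlation between network-mean time series of the individualized networks —
the baseline against which topography covariance is compared on: stability to
global signal regression (mean-normalized RMSE), information overlap on
negative couplings (R-squared of profiles), group-to-individual variability of
negative couplings (1 - r dissimilarity), and developmental sensitivity
(difference of Cohen's d effect maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .development import EffectTable
from .individualize import Parcellation
from .synthgen import Scan
from .topography import R_CLIP, upper_triangle

__all__ = [
    "FcMatrix",
    "conventional_fc",
    "gsr_stability",
    "negative_profile_dissimilarity",
    "profile_overlap_r2",
    "sensitivity_difference",
]


@dataclass(frozen=True)
class FcMatrix:
    """K x K Fisher-z temporal correlation of network-mean series.

    The diagonal is stored as 0 and treated as masked.
    """

    values: np.ndarray
    gsr_flag: bool = False
    subject_id: str = "group"

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("FC matrix must be symmetric")
        iu = np.triu_indices(v.shape[0], 1)
        if not np.all(np.isfinite(v[iu])):
            raise ValueError("FC off-diagonal entries must be finite")

    @property
    def k(self) -> int:
        return self.values.shape[0]


def conventional_fc(scan: Scan, parcellation: Parcellation, gsr: bool = False) -> FcMatrix:
    """Pairwise Fisher-z correlation of network-mean time series."""
    from .preprocess import global_signal_regress

    if gsr:
        scan = global_signal_regress(scan)
    k = parcellation.n_networks
    series = np.empty((scan.n_frames, k))
    for i in range(1, k + 1):
        m = parcellation.mask(i)
        if not m.any():
            raise ValueError(f"network {i} has no vertices")
        series[:, i - 1] = scan.data[:, m].mean(axis=1)
    sd = series.std(axis=0)
    if np.any(sd < 1e-12):
        bad = np.where(sd < 1e-12)[0] + 1
        raise ValueError(f"zero-variance network series: {list(bad)}")
    r = np.corrcoef(series, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FcMatrix(values=z, gsr_flag=gsr, subject_id=scan.meta.subject_id)


def gsr_stability(matrix_gsr: np.ndarray, matrix_nogsr: np.ndarray) -> float:
    """Mean-normalized RMSE between the GSR and non-GSR matrices.

    RMSE over the strict upper triangle, divided by the mean absolute
    upper-triangle entry of the non-GSR matrix (the signed mean can be near
    zero, which would make the ratio unstable).
    """
    a = upper_triangle(np.asarray(matrix_gsr))
    b = upper_triangle(np.asarray(matrix_nogsr))
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    norm = float(np.mean(np.abs(b)))
    if norm < 1e-12:
        raise ValueError("zero normalizer: non-GSR matrix has no signal")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return rmse / norm


def _negative_edge_mask(group_matrix: np.ndarray) -> np.ndarray:
    return upper_triangle(group_matrix) < 0


def negative_profile_dissimilarity(
    group_matrix: np.ndarray, subject_matrices: list[np.ndarray]
) -> np.ndarray:
    """Per-subject 1 - r between group- and individual-level negative couplings.

    The negative-edge set is frozen from the group matrix (group-mean entry
    below zero); subject values on the same edges are compared.
    """
    neg = _negative_edge_mask(np.asarray(group_matrix))
    if neg.sum() < 3:
        raise ValueError("fewer than 3 negative edges in the group matrix")
    g = upper_triangle(np.asarray(group_matrix))[neg]
    out = np.empty(len(subject_matrices))
    for s, m in enumerate(subject_matrices):
        v = upper_triangle(np.asarray(m))[neg]
        out[s] = 1.0 - float(np.corrcoef(g, v)[0, 1])
    return out


def profile_overlap_r2(
    foca_matrix: np.ndarray, fc_matrix: np.ndarray, reference: str = "foca"
) -> np.ndarray:
    """Per-network R-squared between FOCA and FC negative-coupling profiles.

    For each network, its row of couplings to the other K-1 networks is
    restricted to the edges that are negative in the reference method's
    matrix; the squared Pearson correlation between the two methods' values on
    those edges measures shared information.
    """
    a = np.asarray(foca_matrix)
    b = np.asarray(fc_matrix)
    if a.shape != b.shape:
        raise ValueError("aligned matrices required")
    ref = a if reference == "foca" else b
    k = a.shape[0]
    out = np.full(k, np.nan)
    for net in range(k):
        row_a = np.delete(a[net], net)
        row_b = np.delete(b[net], net)
        neg = np.delete(ref[net], net) < 0
        if neg.sum() < 3:
            continue
        r = np.corrcoef(row_a[neg], row_b[neg])[0, 1]
        out[net] = r**2
    if np.all(np.isnan(out)):
        raise ValueError("no network has enough negative couplings")
    return out


def sensitivity_difference(effect_foca: EffectTable, effect_fc: EffectTable) -> np.ndarray:
    """Elementwise difference of developmental effect sizes (d_FOCA - d_FC)."""
    if effect_foca.d.shape != effect_fc.d.shape:
        raise ValueError("effect tables must have the same shape")
    return effect_foca.d - effect_fc.d
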