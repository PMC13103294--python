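"""Synthetic surface-fMRI cohort generator with planted network structure.

The generator emulates the statistical structure that functional topography
covariance analysis (FOCA) estimates: K latent network signals with a signed
correlation (coupling) matrix, a per-vertex network label field with
subject-specific boundary perturbations, a shared global-signal component,
motion spikes expressed as framewise displacement (FD), age-modulated
couplings, and behaviour scores built from coupling features.  A closed-form
oracle (:func:`oracle_foca`) gives the expected noise-free FOCA matrix against
which the estimator can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SurfaceGeometry",
    "EffectSpec",
    "LatentCouplingModel",
    "SubjectMeta",
    "Scan",
    "make_geometry",
    "nearest_psd_correlation",
    "tile_labels",
    "sample_latent_model",
    "simulate_scan",
    "simulate_cohort",
    "oracle_foca",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceGeometry:
    """A cortical-surface stand-in: a rectangular vertex mesh.

    Attributes
    ----------
    vertex_coords : (V, 3) float array, mm
    edges : (E, 2) int array, undirected mesh edges (u < v, no self-loops)
    hemisphere : (V,) array of "L"/"R" labels
    """

    vertex_coords: np.ndarray
    edges: np.ndarray
    hemisphere: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def adjacency(self) -> "scipy.sparse.csr_matrix":
        """Symmetric sparse 0/1 adjacency matrix."""
        from scipy import sparse

        v = self.n_vertices
        u, w = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(len(u))
        a = sparse.coo_matrix((data, (u, w)), shape=(v, v))
        a = a + a.T
        return a.tocsr()

    def neighbours(self) -> list[np.ndarray]:
        adj = self.adjacency().tolil()
        return [np.asarray(r, dtype=int) for r in adj.rows]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertex_coords)):
            raise ValueError("vertex coordinates must be finite")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("adjacency must be irreflexive")


@dataclass(frozen=True)
class EffectSpec:
    """Subject-level effect parameters for the generator.

    Parameters
    ----------
    boundary_shift_rate : fraction of boundary vertices relabelled per subject.
    global_weight : weight g of the shared global-signal component.
    noise_sd : vertex-level white-noise standard deviation.
    age_effects : map (i, j) 1-based network pair -> Fisher-z slope per unit age.
    age_reference : age (same units as SubjectMeta.age) at which age effects
        vanish; couplings at other ages are shifted on the Fisher-z scale by
        ``slope * (age - age_reference)``.
    behaviour_weights : map score name -> {"network": i (1-based),
        "weights": length-K vector applied to Fisher-z couplings of network i,
        "noise_sd": residual SD}.
    """

    boundary_shift_rate: float = 0.0
    global_weight: float = 0.0
    noise_sd: float = 1.0
    age_effects: Mapping[tuple[int, int], float] = field(default_factory=dict)
    age_reference: float = 40.5
    behaviour_weights: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.boundary_shift_rate < 0.5):
            raise ValueError("boundary_shift_rate must lie in [0, 0.5)")
        if self.global_weight < 0:
            raise ValueError("global_weight must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LatentCouplingModel:
    """Ground truth for a synthetic cohort.

    ``coupling`` is the K x K symmetric positive-semidefinite latent signal
    correlation matrix (unit diagonal, signed entries); ``group_labels`` is the
    per-vertex network id in 1..K on ``geometry``.
    """

    k_networks: int
    coupling: np.ndarray
    group_labels: np.ndarray
    geometry: SurfaceGeometry
    effects: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        c = self.coupling
        if c.shape != (self.k_networks, self.k_networks):
            raise ValueError("coupling must be K x K")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("coupling must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("coupling diagonal must be 1")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("coupling must be positive semidefinite")
        counts = np.bincount(self.group_labels, minlength=self.k_networks + 1)[1:]
        if np.any(counts == 0):
            raise ValueError("every network must own at least one vertex")


@dataclass
class SubjectMeta:
    """Per-subject metadata carried with each scan."""

    subject_id: str
    group: str = "adult"  # {"adult", "neonate"}
    age: float = 30.0  # years (adults) or PMA weeks (neonates)
    sex: str = "F"
    mean_fd: float = 0.0
    scan_birth_interval: float = 0.0  # weeks
    behaviour_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be >= 0")


@dataclass
class Scan:
    """A surface-projected BOLD run: T x V data plus an FD trace.

    ``censor_mask`` marks frames retained after scrubbing (all True before).
    ``history`` records applied processing steps (provenance).
    """

    data: np.ndarray  # (T, V)
    tr: float  # seconds
    fd: np.ndarray  # (T,)
    censor_mask: np.ndarray  # (T,) bool
    meta: SubjectMeta
    true_labels: np.ndarray | None = None  # generator truth, 1-based
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.data.shape[0]
        if len(self.fd) != t or len(self.censor_mask) != t:
            raise ValueError("fd and censor_mask must match the frame count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scan data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Scan":
        out = Scan(
            data=kw.get("data", self.data),
            tr=kw.get("tr", self.tr),
            fd=kw.get("fd", self.fd),
            censor_mask=kw.get("censor_mask", self.censor_mask),
            meta=self.meta,
            true_labels=self.true_labels,
            history=list(self.history) + [kw["step"]] if "step" in kw else list(self.history),
        )
        return out


# ---------------------------------------------------------------------------
# geometry and labels
# ---------------------------------------------------------------------------


def make_geometry(n_rows: int, n_cols: int, spacing_mm: float = 2.0, seed: int = 0) -> SurfaceGeometry:
    """Build a rectangular mesh with 4-neighbour adjacency.

    Vertices are numbered row-major; the left half of the columns is labelled
    hemisphere "L", the rest "R".  ``seed`` is accepted for interface symmetry
    (the construction is deterministic).
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if n_rows * n_cols < 16:
        raise ValueError("mesh needs at least 16 vertices")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack(
        [cc.ravel() * spacing_mm, rr.ravel() * spacing_mm, np.zeros(n_rows * n_cols)]
    ).astype(float)
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    right = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    down = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    edges = np.vstack([right, down])
    hemi = np.where(cc.ravel() < n_cols / 2, "L", "R")
    return SurfaceGeometry(vertex_coords=coords, edges=edges, hemisphere=hemi)


def nearest_psd_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix by eigenvalue
    clipping at zero, then rescale to unit diagonal."""
    c = np.asarray(c, dtype=float)
    s = (c + c.T) / 2.0
    w, v = np.linalg.eigh(s)
    w = np.clip(w, 0.0, None)
    p = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(p), 1e-12, None))
    p = p / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return (p + p.T) / 2.0


def _factor_pair(k: int) -> tuple[int, int]:
    best = (1, k)
    for a in range(1, int(np.sqrt(k)) + 1):
        if k % a == 0:
            best = (a, k // a)
    return best


def tile_labels(geometry: SurfaceGeometry, k: int, n_rows: int, n_cols: int) -> np.ndarray:
    """Tile the grid into K contiguous rectangular patches (1-based labels)."""
    a, b = _factor_pair(k)
    if a > n_rows or b > n_cols:
        raise ValueError(f"cannot tile a {n_rows}x{n_cols} grid into {k} patches")
    row_band = np.minimum((np.arange(n_rows) * a) // n_rows, a - 1)
    col_band = np.minimum((np.arange(n_cols) * b) // n_cols, b - 1)
    lab = row_band[:, None] * b + col_band[None, :] + 1
    return lab.ravel().astype(int)


def sample_latent_model(
    k_networks: int,
    geometry: SurfaceGeometry,
    coupling_spec: np.ndarray,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
) -> LatentCouplingModel:
    """Create a :class:`LatentCouplingModel` from a target coupling matrix.

    ``coupling_spec`` must be symmetric with unit diagonal; it is repaired to
    the nearest PSD correlation matrix.  Network labels tile the grid into K
    contiguous patches.
    """
    spec = np.asarray(coupling_spec, dtype=float)
    if spec.shape != (k_networks, k_networks):
        raise ValueError("coupling_spec must be K x K")
    if not np.allclose(spec, spec.T, atol=1e-8):
        raise ValueError("coupling_spec must be symmetric")
    if not np.allclose(np.diag(spec), 1.0, atol=1e-8):
        raise ValueError("coupling_spec must have unit diagonal")
    coupling = nearest_psd_correlation(spec)
    # recover grid shape from the row-major coordinates
    xs = geometry.vertex_coords[:, 0]
    n_cols = int(np.sum(geometry.vertex_coords[:, 1] == geometry.vertex_coords[0, 1]))
    n_rows = geometry.n_vertices // n_cols
    labels = tile_labels(geometry, k_networks, n_rows, n_cols)
    eff = effect_spec if effect_spec is not None else EffectSpec()
    return LatentCouplingModel(
        k_networks=k_networks,
        coupling=coupling,
        group_labels=labels,
        geometry=geometry,
        effects=eff,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _subject_coupling(model: LatentCouplingModel, age: float) -> np.ndarray:
    """Coupling matrix for one subject: age effects applied on the Fisher-z
    scale of the targeted entries, then PSD-repaired."""
    eff = model.effects
    if not eff.age_effects:
        return model.coupling
    c = model.coupling.copy()
    delta = age - eff.age_reference
    for (i, j), slope in eff.age_effects.items():
        z = np.arctanh(np.clip(c[i - 1, j - 1], -1 + 1e-7, 1 - 1e-7))
        r = np.tanh(z + slope * delta)
        c[i - 1, j - 1] = c[j - 1, i - 1] = r
    return nearest_psd_correlation(c)


def perturb_labels(
    model: LatentCouplingModel, rng: np.random.Generator
) -> np.ndarray:
    """Flip a fraction of boundary vertices to an adjacent network's label."""
    rate = model.effects.boundary_shift_rate
    labels = model.group_labels.copy()
    if rate <= 0:
        return labels
    nbrs = model.geometry.neighbours()
    boundary = [
        v for v in range(len(labels)) if any(labels[u] != labels[v] for u in nbrs[v])
    ]
    n_flip = int(round(rate * len(boundary)))
    if n_flip == 0:
        return labels
    chosen = rng.choice(len(boundary), size=n_flip, replace=False)
    for c in chosen:
        v = boundary[c]
        other = [labels[u] for u in nbrs[v] if labels[u] != model.group_labels[v]]
        if other:
            labels[v] = other[rng.integers(len(other))]
    return labels


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) series."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - rho**2)
    e = rng.standard_normal(n) * innov_sd
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    return x


def _draw_fd(n: int, rng: np.random.Generator, max_tries: int = 20) -> np.ndarray:
    """FD trace: low baseline with occasional >0.5 mm spikes.

    Retries if fewer than 50 frames survive the 0.5-mm rule (a degenerate
    all-spike draw), erroring after ``max_tries``.
    """
    for _ in range(max_tries):
        base = np.abs(rng.normal(0.05, 0.02, size=n))
        spikes = rng.random(n) < 0.05
        fd = np.where(spikes, np.abs(rng.normal(0.8, 0.2, size=n)), base)
        if np.sum(fd <= 0.5) >= min(50, n):
            return fd
    raise RuntimeError("could not draw a usable FD trace (all-spike draws)")


def simulate_scan(
    model: LatentCouplingModel,
    meta: SubjectMeta,
    n_frames: int = 300,
    tr: float = 2.0,
    seed: int = 0,
) -> Scan:
    """Simulate one subject's surface BOLD run.

    Latent network signals are multivariate normal with the subject's coupling
    matrix (age effects applied on the Fisher-z scale); each vertex carries its
    network's signal plus ``g``-weighted global AR(1) signal plus white noise.
    Subject labels perturb the group labels at network boundaries.
    """
    if n_frames < 50:
        raise ValueError("n_frames must be >= 50")
    rng = np.random.default_rng(seed)
    eff = model.effects
    labels = perturb_labels(model, rng)
    c = _subject_coupling(model, meta.age)
    chol = np.linalg.cholesky(c + 1e-10 * np.eye(model.k_networks))
    s = rng.standard_normal((n_frames, model.k_networks)) @ chol.T
    data = s[:, labels - 1].astype(float)
    if eff.global_weight > 0:
        g = _ar1(n_frames, 0.3, rng)
        data = data + eff.global_weight * g[:, None]
    if eff.noise_sd > 0:
        data = data + eff.noise_sd * rng.standard_normal(data.shape)
    fd = _draw_fd(n_frames, rng)
    meta.mean_fd = float(np.mean(fd))
    _assign_behaviour(meta, c, eff, rng)
    return Scan(
        data=data,
        tr=tr,
        fd=fd,
        censor_mask=np.ones(n_frames, dtype=bool),
        meta=meta,
        true_labels=labels,
        history=[f"simulate(seed={seed})"],
    )


def _assign_behaviour(
    meta: SubjectMeta, coupling: np.ndarray, eff: EffectSpec, rng: np.random.Generator
) -> None:
    for name, spec in eff.behaviour_weights.items():
        i = int(spec["network"]) - 1
        w = np.asarray(spec["weights"], dtype=float)
        z = np.arctanh(np.clip(coupling[i], -1 + 1e-7, 1 - 1e-7))
        score = float(w @ z) + float(spec.get("noise_sd", 0.0)) * rng.standard_normal()
        meta.behaviour_scores[name] = score


def simulate_cohort(
    model: LatentCouplingModel,
    n_subjects: int,
    group: str = "adult",
    age_range: tuple[float, float] = (20.0, 40.0),
    n_frames: int = 300,
    tr: float = 2.0,
    seed: int = 0,
) -> list[Scan]:
    """Simulate a cohort of subjects with ages uniform over ``age_range``."""
    rng = np.random.default_rng(seed)
    scans = []
    for i in range(n_subjects):
        age = float(rng.uniform(*age_range))
        meta = SubjectMeta(
            subject_id=f"{group}{i + 1:03d}",
            group=group,
            age=age,
            sex="F" if rng.random() < 0.5 else "M",
            scan_birth_interval=float(rng.uniform(0.0, 4.0)),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scans.append(simulate_scan(model, meta, n_frames=n_frames, tr=tr, seed=sub_seed))
    return scans


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def oracle_foca(model: LatentCouplingModel, fisher_z: bool = True) -> np.ndarray:
    """Expected FOCA matrix in the noise-free limit.

    In the absence of noise, global signal, and boundary perturbation, the
    seed-map value of network i at vertex v is the latent correlation
    C[i, label(v)]; the estimator works on Fisher-z maps, so the expectation
    applies the same clipped arctanh before correlating the piecewise-constant
    maps across vertices (network sizes act as weights).  With ``fisher_z``
    False the maps are correlated on the raw r scale; for C = I the two
    agree exactly (the transform is affine on two-valued indicator maps).
    """
    labels = model.group_labels
    counts = np.bincount(labels, minlength=model.k_networks + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("every network must own at least one vertex")
    t = model.coupling[:, labels - 1]  # (K, V) expanded maps
    if fisher_z:
        t = np.arctanh(np.clip(t, -1 + 1e-7, 1 - 1e-7))
    out = np.corrcoef(t)
    np.fill_diagonal(out, 1.0)
    return out
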