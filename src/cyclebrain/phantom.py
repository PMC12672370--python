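"""Synthetic structural-image stacks with hormone-coupled planted patterns.

Emulates the data that enters the spatiotemporal decomposition: per-session,
spatially normalized, smoothed gray-matter maps (or vertex thickness vectors)
for densely sampled individuals.  Each stack is a static anatomical baseline
plus a small number of planted spatial patterns whose session-wise loadings
are either coupled to square-root hormone levels or evolve as smooth AR(1)
series, plus voxel noise.

The default study design mirrors the dense-sampling conditions of the
reference study: four female individuals with 25 / 30 / 24 / 25 sessions
(weekday sampling with weekend gaps for three of them, consecutive days for
the fourth), a 24x24x24 voxel phantom at 2 mm, and three planted components
at target variance fractions 0.50 / 0.20 / 0.10 with the leading component
coupled to progesterone in typical cycles and to estradiol in the
endometriosis and oral-contraceptive cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .hormones import (
    TEMPLATES,
    HormoneSeries,
    simulate_cycle,
    sqrt_transform,
    standardize,
)

__all__ = [
    "VolumeGeometry",
    "VertexGeometry",
    "PlantedModel",
    "SessionStack",
    "make_phantom_mask",
    "make_lattice_geometry",
    "smooth_within_mask",
    "simulate_stack",
    "default_study_design",
    "weekday_session_days",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumeGeometry:
    """Regular 3D voxel grid with a binary analysis mask."""

    shape: tuple[int, int, int]
    voxel_mm: float
    mask: np.ndarray  # 3D bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")

    @property
    def n_locations(self) -> int:
        return int(self.mask.sum())

    @property
    def kind(self) -> str:
        return "volume"

    def matches(self, other) -> bool:
        return (
            isinstance(other, VolumeGeometry)
            and self.shape == other.shape
            and self.voxel_mm == other.voxel_mm
            and np.array_equal(self.mask, other.mask)
        )

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a mask-length vector back into the 3D grid."""
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol


@dataclass
class VertexGeometry:
    """Surface-like graph geometry: vertices plus an adjacency edge list."""

    n_vertices: int
    edges: np.ndarray  # (E, 2) int, undirected

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if self.edges.size and self.edges.max() >= self.n_vertices:
            raise ValueError("edge endpoint out of range")

    @property
    def n_locations(self) -> int:
        return self.n_vertices

    @property
    def kind(self) -> str:
        return "vertex"

    def matches(self, other) -> bool:
        return (
            isinstance(other, VertexGeometry)
            and self.n_vertices == other.n_vertices
            and np.array_equal(self.edges, other.edges)
        )


@dataclass
class PlantedModel:
    """Ground truth of a simulated study.

    ``spatial_patterns`` rows are unit-norm and mutually orthogonal;
    ``loading_series`` maps individual_id to a (sessions, K) amplitude matrix.
    Components whose coupling names a hormone have loadings perfectly
    correlated with the standardized square-root hormone level before noise.
    """

    spatial_patterns: np.ndarray                  # (K, V)
    loading_series: dict[str, np.ndarray]         # id -> (n_i, K)
    coupling: list[dict] = field(default_factory=list)
    noise_sd: float = 0.0
    smoothing_fwhm: float = 0.0
    target_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.spatial_patterns, dtype=float)
        G = S @ S.T
        if not np.allclose(G, np.eye(S.shape[0]), atol=1e-8):
            raise ValueError("spatial patterns must be orthonormal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SessionStack:
    """One individual's sessions-by-locations data matrix."""

    individual_id: str
    days: np.ndarray
    data: np.ndarray           # (n_sessions, n_locations)
    geometry: VolumeGeometry | VertexGeometry

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != self.days.size:
            raise ValueError("row count must equal number of days")
        if self.data.shape[1] != self.geometry.n_locations:
            raise ValueError("column count must equal in-mask location count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("missing/non-finite values in stack")
        if self.geometry.kind == "volume" and np.any(self.data < 0):
            raise ValueError("volumetric values must be nonnegative")

    @property
    def n_sessions(self) -> int:
        return int(self.days.size)


def make_phantom_mask(
    shape: tuple[int, int, int], voxel_mm: float = 2.0
) -> VolumeGeometry:
    """Ellipsoidal gray-matter phantom mask occupying ~38% of the box."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError(f"each dimension must be >= 8, got {shape}")
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    r2 = sum(
        ((g - (s - 1) / 2.0) / (0.45 * s)) ** 2 for g, s in zip(grids, shape)
    )
    return VolumeGeometry(shape=shape, voxel_mm=float(voxel_mm), mask=r2 <= 1.0)


def make_lattice_geometry(nrow: int = 32, ncol: int = 32) -> VertexGeometry:
    """2D lattice graph with 4-neighbour adjacency (surface stand-in)."""
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    edges = np.concatenate(
        [
            np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1),
            np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1),
        ]
    )
    return VertexGeometry(n_vertices=nrow * ncol, edges=edges)


def smooth_within_mask(
    values: np.ndarray, geometry: VolumeGeometry, fwhm_mm: float
) -> np.ndarray:
    """Gaussian-smooth a mask-length vector with edge renormalization.

    The kernel is renormalized inside the mask (smooth(data*mask)/smooth(mask))
    so the mask-mean intensity is preserved at mask edges.
    """
    if fwhm_mm <= 0:
        return np.asarray(values, dtype=float)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / geometry.voxel_mm
    mask = geometry.mask
    vol = np.zeros(geometry.shape)
    vol[mask] = values
    num = gaussian_filter(vol, sigma_vox)
    den = gaussian_filter(mask.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    return sm[mask]


def _smooth_random_field(
    rng: np.random.Generator, geometry: VolumeGeometry, sigma_vox: float = 2.5
) -> np.ndarray:
    field3d = gaussian_filter(rng.standard_normal(geometry.shape), sigma_vox)
    return field3d[geometry.mask]


def simulate_stack(
    planted: PlantedModel,
    hormones: HormoneSeries,
    geometry: VolumeGeometry | VertexGeometry,
    baseline: np.ndarray,
    seed: int,
) -> SessionStack:
    """Simulate one individual's session stack.

    X(t) = baseline + sum_k a_k(t) * S_k + iid Gaussian noise, optionally
    Gaussian-smoothed within the mask at ``planted.smoothing_fwhm`` (volumes
    only).  Deterministic given ``seed``.
    """
    loadings = planted.loading_series
    if isinstance(loadings, dict):
        if hormones.individual_id not in loadings:
            raise KeyError(
                f"no loading series for individual {hormones.individual_id!r}"
            )
        A = np.asarray(loadings[hormones.individual_id], dtype=float)
    else:
        A = np.asarray(loadings, dtype=float)
    S = np.asarray(planted.spatial_patterns, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    n = len(hormones)
    if A.shape != (n, S.shape[0]):
        raise ValueError(
            f"loading series shape {A.shape} does not match "
            f"{n} sessions x {S.shape[0]} components"
        )
    if baseline.shape != (geometry.n_locations,):
        raise ValueError("baseline must be a mask-length vector")
    if S.shape[1] != geometry.n_locations:
        raise ValueError("spatial patterns do not match geometry")

    rng = np.random.default_rng(seed)
    X = baseline[None, :] + A @ S
    if planted.noise_sd > 0:
        X = X + planted.noise_sd * rng.standard_normal(X.shape)
    if planted.smoothing_fwhm > 0:
        if geometry.kind != "volume":
            raise ValueError("FWHM smoothing applies to volumetric stacks only")
        X = np.stack(
            [smooth_within_mask(row, geometry, planted.smoothing_fwhm) for row in X]
        )
    if geometry.kind == "volume":
        X = np.clip(X, 0.0, None)
    return SessionStack(
        individual_id=hormones.individual_id,
        days=hormones.day,
        data=X,
        geometry=geometry,
    )


def weekday_session_days(n_weeks: int = 5, exclude: tuple[int, ...] = ()) -> np.ndarray:
    """Monday-to-Friday test days over consecutive weeks (1-based)."""
    days = np.concatenate([7 * w + np.arange(1, 6) for w in range(n_weeks)])
    return days[~np.isin(days, exclude)]


_DESIGN = [
    # (individual template, session-day rule, coupled hormone)
    ("typical", ("weekday", ()), "progesterone"),
    ("typical_28andme", ("daily", 30), "progesterone"),
    ("endometriosis", ("weekday", (8,)), "estradiol"),
    ("oc", ("weekday", ()), "estradiol"),
]


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.5) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = np.sqrt(1.0 - rho**2) * rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return standardize(x)


def default_study_design(
    seed: int,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_mm: float = 2.0,
    noise_share: float = 0.2,
    target_fractions: tuple[float, float, float] = (0.50, 0.20, 0.10),
) -> tuple[list[HormoneSeries], list[SessionStack], PlantedModel]:
    """Simulate the full four-individual study.

    Session counts are 25 (typical, weekday sampling), 30 (28andMe-style,
    consecutive days), 24 (endometriosis, weekday sampling with test day 8
    excluded) and 25 (OC).  Three orthonormal smooth spatial patterns are
    planted; component 1 loadings equal the standardized square-root level of
    the individual's dominant hormone (progesterone in typical cycles,
    estradiol in the endometriosis and OC cycles), components 2-3 are smooth
    AR(1) series orthogonalized against the coupled loadings.  Loading norms
    are scaled so the planted components hold ``target_fractions`` of the
    expected total centered variance and iid voxel noise holds the remainder.

    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    geometry = make_phantom_mask(grid_shape, voxel_mm)
    V = geometry.n_locations
    K = len(target_fractions)

    # orthonormal smooth spatial patterns
    F = np.stack([_smooth_random_field(rng, geometry) for _ in range(K)], axis=1)
    F -= F.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(F)
    Q *= np.sign(np.diag(R))[None, :]
    S = Q.T  # (K, V)

    hormone_series: list[HormoneSeries] = []
    raw_loadings: list[np.ndarray] = []
    coupling: list[dict] = [
        {"hormone": "by_individual", "strength": 1.0},
        {"hormone": "none", "strength": 0.0},
        {"hormone": "none", "strength": 0.0},
    ]
    for template, day_rule, hormone_name in _DESIGN:
        if day_rule[0] == "weekday":
            days = weekday_session_days(5, exclude=day_rule[1])
        else:
            days = np.arange(1, day_rule[1] + 1)
        config = TEMPLATES(template, seed=int(rng.integers(2**31 - 1)))
        series = simulate_cycle(config, days)
        hormone_series.append(series)
        n_i = len(series)
        hormone = getattr(series, hormone_name)
        a = np.empty((n_i, K))
        a[:, 0] = standardize(sqrt_transform(hormone))
        for k in range(1, K):
            a[:, k] = _ar1(rng, n_i)
        raw_loadings.append(a)

    # Concatenate, orthogonalize the uncoupled loadings against earlier ones,
    # and scale norms so planted variance shares are exact.
    A = np.vstack(raw_loadings)  # (N, K), each column block-standardized
    N = A.shape[0]
    n_ind = len(raw_loadings)
    for k in range(1, K):
        for j in range(k):
            A[:, k] -= (A[:, j] @ A[:, k]) / (A[:, j] @ A[:, j]) * A[:, j]
    # expected noise sum of squares after per-individual centering
    noise_sd = 0.01
    noise_ss = (N - n_ind) * V * noise_sd**2
    total_ss = noise_ss / noise_share if noise_share > 0 else 1.0
    for k in range(K):
        # noise-free: norms proportional to the target fractions so the
        # planted singular values stay distinct and recoverable
        target = target_fractions[k] * total_ss
        A[:, k] *= np.sqrt(target / (A[:, k] @ A[:, k]))

    loading_series: dict[str, np.ndarray] = {}
    row = 0
    for series, _ in zip(hormone_series, raw_loadings):
        n_i = len(series)
        loading_series[series.individual_id] = A[row : row + n_i]
        row += n_i

    planted = PlantedModel(
        spatial_patterns=S,
        loading_series=loading_series,
        coupling=coupling,
        noise_sd=noise_sd if noise_share > 0 else 0.0,
        smoothing_fwhm=0.0,
        target_fractions=np.asarray(target_fractions),
    )

    stacks = []
    for series in hormone_series:
        baseline = 0.45 + 0.08 * _smooth_random_field(rng, geometry)
        baseline = np.clip(baseline, 0.05, 0.95)
        stacks.append(
            simulate_stack(
                planted,
                series,
                geometry,
                baseline,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return hormone_series, stacks, planted


def male_control_design(
    seed: int,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_mm: float = 2.0,
    noise_share: float = 0.2,
    target_fractions: tuple[float, float, float] = (0.50, 0.20, 0.10),
) -> tuple[HormoneSeries, SessionStack, PlantedModel]:
    """Single male control: 25 weekday sessions, no hormone coupling.

    Structural dynamics are planted exactly as in the female design (three
    orthonormal smooth patterns at the same variance-fraction targets) but
    every loading series is an uncoupled smooth AR(1) process — the brain
    fluctuates while hormones stay low and weakly varying, so no genuine
    brain-hormone association exists.
    """
    rng = np.random.default_rng(seed)
    geometry = make_phantom_mask(grid_shape, voxel_mm)
    V = geometry.n_locations
    K = len(target_fractions)

    F = np.stack([_smooth_random_field(rng, geometry) for _ in range(K)], axis=1)
    F -= F.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(F)
    Q *= np.sign(np.diag(R))[None, :]
    S = Q.T

    days = weekday_session_days(5)
    config = TEMPLATES("male", seed=int(rng.integers(2**31 - 1)))
    series = simulate_cycle(config, days)
    n = len(series)

    A = np.stack([_ar1(rng, n) for _ in range(K)], axis=1)
    for k in range(1, K):
        for j in range(k):
            A[:, k] -= (A[:, j] @ A[:, k]) / (A[:, j] @ A[:, j]) * A[:, j]
    noise_sd = 0.01
    noise_ss = (n - 1) * V * noise_sd**2
    total_ss = noise_ss / noise_share if noise_share > 0 else 1.0
    for k in range(K):
        A[:, k] *= np.sqrt(target_fractions[k] * total_ss / (A[:, k] @ A[:, k]))

    planted = PlantedModel(
        spatial_patterns=S,
        loading_series={series.individual_id: A},
        coupling=[{"hormone": "none", "strength": 0.0}] * K,
        noise_sd=noise_sd if noise_share > 0 else 0.0,
        smoothing_fwhm=0.0,
        target_fractions=np.asarray(target_fractions),
    )
    baseline = np.clip(0.45 + 0.08 * _smooth_random_field(rng, geometry), 0.05, 0.95)
    stack = simulate_stack(
        planted, series, geometry, baseline, seed=int(rng.integers(2**31 - 1))
    )
    return series, stack, planted
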