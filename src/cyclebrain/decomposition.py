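"""SVD spatiotemporal decomposition of concatenated structural image stacks.

Sessions from several densely sampled individuals are stacked row-wise into
one matrix (rows = sessions, columns = in-mask voxels or vertices), centered,
and decomposed with a thin singular value decomposition.  Each component is a
*spatiotemporal pattern*: a unit-norm spatial weight map (right singular
vector) together with per-session temporal scores (left singular vector).
The variance fraction of component k is sigma_k^2 / sum_j sigma_j^2.
Components explaining at least ~10% of the variance are retained for the
temporal and hormone-association analyses; spatial maps are displayed after
soft thresholding to the +/-[0.01, 0.1] weight range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ConcatMatrix",
    "SpatioTemporalPattern",
    "SpatioTemporalSVD",
    "concatenate_and_center",
    "svd_decompose",
    "select_components",
    "threshold_spatial",
    "standardize_temporal",
]


@dataclass
class ConcatMatrix:
    """Centered sessions-by-locations matrix with individual block structure."""

    X: np.ndarray
    blocks: list[tuple[str, slice]]   # (individual_id, row slice) in input order
    centering: str                    # "per_individual" | "global"

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    @property
    def n_locations(self) -> int:
        return self.X.shape[1]


@dataclass
class SpatioTemporalPattern:
    """One SVD component of the concatenated stack."""

    index: int                    # 1-based component number
    spatial: np.ndarray           # unit-norm weights over locations
    temporal: np.ndarray          # unit-norm scores over all sessions
    singular_value: float
    variance_fraction: float
    temporal_std: np.ndarray      # per-individual z-scored copy of `temporal`
    retained: bool = True


def concatenate_and_center(stacks, centering: str = "per_individual") -> ConcatMatrix:
    """Stack individuals' session matrices row-wise and center columns.

    ``stacks`` is a sequence of objects with ``individual_id``, ``data``
    (sessions x locations) and a shared geometry (see brain_sim.SessionStack);
    bare (id, array) tuples are accepted too.

    Per-individual centering subtracts each individual's own voxel means,
    removing static anatomy so the shared spatial patterns reflect
    within-cycle change; global centering subtracts the grand voxel means.
    """
    if centering not in ("per_individual", "global"):
        raise ValueError(f"unknown centering {centering!r}")
    items = []
    for s in stacks:
        if hasattr(s, "individual_id"):
            items.append((s.individual_id, np.asarray(s.data, dtype=float), s))
        else:
            ind, data = s
            items.append((str(ind), np.asarray(data, dtype=float), None))
    if not items:
        raise ValueError("need at least one stack")
    ids = [ind for ind, _, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate individual_id in {ids}")
    ncols = items[0][1].shape[1]
    geoms = [s.geometry for _, _, s in items if s is not None and hasattr(s, "geometry")]
    for g in geoms[1:]:
        if not g.matches(geoms[0]):
            raise ValueError("stacks have mismatching geometry/mask")
    for ind, data, _ in items:
        if data.ndim != 2 or data.shape[1] != ncols:
            raise ValueError(
                f"stack {ind!r} has {data.shape} columns, expected {ncols}"
            )

    X = np.vstack([data for _, data, _ in items])
    blocks: list[tuple[str, slice]] = []
    row = 0
    for ind, data, _ in items:
        blocks.append((ind, slice(row, row + data.shape[0])))
        row += data.shape[0]

    if centering == "per_individual":
        X = X.copy()
        for _, sl in blocks:
            X[sl] -= X[sl].mean(axis=0, keepdims=True)
    else:
        X = X - X.mean(axis=0, keepdims=True)
    return ConcatMatrix(X=X, blocks=blocks, centering=centering)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> None:
    """Make the largest-magnitude spatial entry of each component positive."""
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0


def svd_decompose(cm: ConcatMatrix) -> list[SpatioTemporalPattern]:
    """Full thin SVD of the centered concatenated matrix.

    Components are ordered by descending singular value with a deterministic
    sign convention (largest-magnitude spatial weight positive).
    """
    X = cm.X
    if X.shape[0] < 2:
        raise ValueError("need at least 2 sessions")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in data matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    _fix_signs(U, Vt)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("data matrix is identically zero after centering")
    patterns = []
    for k in range(s.size):
        u = U[:, k]
        patterns.append(
            SpatioTemporalPattern(
                index=k + 1,
                spatial=Vt[k],
                temporal=u,
                singular_value=float(s[k]),
                variance_fraction=float(s[k] ** 2 / total),
                temporal_std=standardize_temporal(u, cm.blocks),
            )
        )
    return patterns


def select_components(
    patterns: list[SpatioTemporalPattern], min_fraction: float = 0.095
) -> list[SpatioTemporalPattern]:
    """Retain leading components with variance fraction >= ``min_fraction``.

    The default 0.095 implements a >=10%-after-rounding retention rule.  The
    top component is always retained (with a warning if it falls below the
    threshold).
    """
    fractions = [p.variance_fraction for p in patterns]
    if any(np.diff(fractions) > 1e-12):
        raise ValueError("patterns must be ordered by descending variance fraction")
    kept = [p for p in patterns if p.variance_fraction >= min_fraction]
    if not kept:
        warnings.warn(
            "top component below the retention threshold; retaining it anyway",
            stacklevel=2,
        )
        kept = [patterns[0]]
    for p in patterns:
        p.retained = p in kept
    return kept


def threshold_spatial(
    spatial: np.ndarray, low: float = 0.01, high: float = 0.1
) -> np.ndarray:
    """Display-threshold a spatial weight map.

    Weights with magnitude below ``low`` are zeroed (minimal contribution);
    magnitudes above ``high`` are clipped to the color-bar limit.  Used for
    maps and reports only, never for statistics.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    w = np.asarray(spatial, dtype=float).copy()
    w[np.abs(w) < low] = 0.0
    return np.clip(w, -high, high)


def standardize_temporal(temporal: np.ndarray, blocks) -> np.ndarray:
    """Z-score temporal scores within each individual's session block."""
    u = np.asarray(temporal, dtype=float)
    out = np.empty_like(u)
    for ind, sl in blocks:
        seg = u[sl]
        if seg.size < 2:
            raise ValueError(f"block {ind!r} has fewer than 2 sessions")
        sd = seg.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant temporal scores in block {ind!r}")
        out[sl] = (seg - seg.mean()) / sd
    return out


class SpatioTemporalSVD(TransformerMixin, BaseEstimator):
    """Concatenated-SVD extraction of spatiotemporal brain patterns.

    An sklearn-style transformer: ``fit`` concatenates and centers the
    individuals' session stacks, computes the SVD and selects the retained
    components; ``transform`` projects (new) session data onto the retained
    spatial patterns.

    Parameters
    ----------
    centering : {"per_individual", "global"}
        Column-centering scheme applied before the SVD.
    min_fraction : float
        Variance-fraction retention threshold (0.095 = 10% after rounding).

    Attributes
    ----------
    patterns_ : list of SpatioTemporalPattern
        All components, descending variance fraction.
    retained_ : list of SpatioTemporalPattern
        The components passing the retention rule.
    components_ : ndarray (n_retained, n_locations)
        Retained spatial patterns, unit norm, sign-fixed.
    variance_fractions_ : ndarray
        Variance fraction of every component.
    blocks_ : list of (individual_id, slice)
    """

    def __init__(self, centering: str = "per_individual", min_fraction: float = 0.095):
        self.centering = centering
        self.min_fraction = min_fraction

    def fit(self, stacks, y=None):
        cm = concatenate_and_center(stacks, self.centering)
        self.concat_ = cm
        self.patterns_ = svd_decompose(cm)
        self.retained_ = select_components(self.patterns_, self.min_fraction)
        self.components_ = np.vstack([p.spatial for p in self.retained_])
        self.singular_values_ = np.array([p.singular_value for p in self.patterns_])
        self.variance_fractions_ = np.array(
            [p.variance_fraction for p in self.patterns_]
        )
        self.blocks_ = cm.blocks
        return self

    def transform(self, X):
        """Project sessions-by-locations data onto retained spatial patterns."""
        if not hasattr(self, "components_"):
            raise RuntimeError("SpatioTemporalSVD is not fitted")
        X = np.asarray(X, dtype=float)
        return X @ self.components_.T
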