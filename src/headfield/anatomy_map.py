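"""Affine transforms and cross-anatomy location matching.

Head models built from different anatomies live in different native
coordinate frames.  To compare them point-by-point, every anatomy is mapped
into the native space of the reference head by a chain of affine transforms
(rigid scanner-to-native transforms, full 12-parameter native-to-template
normalisations, or a least-squares affine fitted to matched surface points),
and each reference cortical location is paired with the nearest transformed
location of the approximate anatomy.  Only coordinates are ever transformed;
lead-field values are never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InvalidTransformError

__all__ = [
    "AffineTransform",
    "CorrespondenceMap",
    "apply_affine",
    "fit_affine_surface",
    "match_locations",
]


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous transform of world (mm) coordinates.

    ``kind`` is ``"rigid6"`` (rotation + translation) or ``"affine12"``
    (full linear map + translation).  The bottom row must be (0,0,0,1) and
    the linear block must be invertible; rigid transforms must additionally
    have an orthonormal, non-reflecting rotation block.
    """

    matrix: np.ndarray
    kind: str = "affine12"
    residual_rms: float | None = field(default=None, compare=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise InvalidTransformError("bottom row must be (0, 0, 0, 1)")
        det = np.linalg.det(m[:3, :3])
        if abs(det) < 1e-12:
            raise InvalidTransformError("linear block is singular")
        if self.kind == "rigid6":
            r = m[:3, :3]
            if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or det < 0:
                raise InvalidTransformError(
                    "rigid6 requires an orthonormal, non-reflecting rotation block"
                )
        elif self.kind != "affine12":
            raise InvalidTransformError(f"unknown transform kind {self.kind!r}")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, kind: str = "rigid6") -> "AffineTransform":
        return cls(np.eye(4), kind=kind)

    @classmethod
    def from_linear(cls, linear, translation=(0.0, 0.0, 0.0), kind="affine12"):
        m = np.eye(4)
        m[:3, :3] = np.asarray(linear, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m, kind=kind)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.linear))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.linear.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), kind=self.kind)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        kind = "rigid6" if self.kind == other.kind == "rigid6" else "affine12"
        return AffineTransform(self.matrix @ other.matrix, kind=kind)


def apply_affine(transform: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`AffineTransform.apply`."""
    return transform.apply(points)


def fit_affine_surface(ref_points, moving_points) -> AffineTransform:
    """Least-squares 12-parameter affine mapping ``moving_points`` onto ``ref_points``.

    Point correspondence is assumed known (e.g. electrode-to-electrode).  The
    fit minimises sum ||T·moving − ref||² and stores the per-point RMS
    residual on the returned transform.  Requires at least four non-coplanar
    pairs; degenerate configurations raise :class:`InvalidTransformError`.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(moving_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InvalidTransformError("need matching (n, 3) point arrays")
    n = ref.shape[0]
    if n < 4:
        raise InvalidTransformError("need at least 4 point pairs")
    design = np.hstack([mov, np.ones((n, 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 4:
        raise InvalidTransformError("point configuration is coplanar/degenerate")
    theta, *_ = np.linalg.lstsq(design, ref, rcond=None)
    m = np.eye(4)
    m[:3, :3] = theta[:3].T
    m[:3, 3] = theta[3]
    resid = design @ theta - ref
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(m, kind="affine12", residual_rms=rms)


@dataclass(frozen=True)
class CorrespondenceMap:
    """For each reference location, the nearest approximate location.

    ``appr_indices[i]`` is the index (in the approximate source space) matched
    to reference location ``i``; ``distances[i]`` the Euclidean distance in mm
    after the transform chain.
    """

    appr_indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.appr_indices, dtype=int)
        d = np.asarray(self.distances, dtype=float)
        if idx.shape != d.shape or idx.ndim != 1:
            raise ValueError("indices and distances must be matching 1-D arrays")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "appr_indices", idx)
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return len(self.appr_indices)

    @classmethod
    def identity(cls, n: int) -> "CorrespondenceMap":
        return cls(np.arange(n), np.zeros(n))


def _points_of(space) -> np.ndarray:
    locs = getattr(space, "locations", space)
    return np.asarray(locs, dtype=float)


def match_locations(ref_space, appr_space, chain=()) -> CorrespondenceMap:
    """Nearest-point correspondence from a reference to an approximate source space.

    ``chain`` is a sequence of :class:`AffineTransform` applied in order to the
    approximate locations, mapping them into the reference head's native
    space.  Each reference location is matched to the exactly nearest
    transformed approximate location (Euclidean distance); exact ties are
    broken to the lowest approximate index.
    """
    ref = _points_of(ref_space)
    appr = _points_of(appr_space)
    if ref.size == 0 or appr.size == 0:
        raise ValueError("source spaces must be non-empty")
    for t in chain:
        appr = t.apply(appr)
    tree = cKDTree(appr)
    k = min(len(appr), 8)
    dists, idx = tree.query(ref, k=k)
    if k == 1:
        return CorrespondenceMap(np.atleast_1d(idx), np.atleast_1d(dists))
    dmin = dists[:, 0]
    tol = 1e-9 * (1.0 + dmin)
    tied = dists <= (dmin + tol)[:, None]
    candidates = np.where(tied, idx, len(appr))
    best = candidates.min(axis=1)
    return CorrespondenceMap(best, dmin)
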