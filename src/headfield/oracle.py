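"""Analytic potential of bipolar current injection on a homogeneous sphere.

Independent correctness oracle for the numerical solver: for a homogeneous
conducting sphere of radius R (insulated surface) with a point current source
at surface direction ``a`` and an equal sink at ``b``, the interior potential
has the classical Legendre expansion

    V(r) = I / (4 pi sigma R) * sum_{n>=1} (2n+1)/n * (|r|/R)^n
           * [P_n(cos gamma_a) - P_n(cos gamma_b)]

with gamma the angle between the evaluation point and the electrode
direction.  Units: radius in mm, current in mA, conductivity in S/m,
potential in volts (mm -> m conversion happens internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import EvaluationError, InvalidGeometryError, TruncationWarning

__all__ = ["SphereSpec", "sphere_potential"]


@dataclass(frozen=True)
class SphereSpec:
    """Homogeneous sphere with a bipolar surface electrode pair."""

    radius_mm: float
    sigma: float
    electrode_a: np.ndarray
    electrode_b: np.ndarray
    current_mA: float = 1.0
    n_terms: int = 200

    def __post_init__(self):
        if self.radius_mm <= 0 or self.sigma <= 0:
            raise InvalidGeometryError("radius and conductivity must be positive")
        if self.n_terms < 1:
            raise InvalidGeometryError("n_terms must be >= 1")
        a = np.asarray(self.electrode_a, dtype=float)
        b = np.asarray(self.electrode_b, dtype=float)
        for v in (a, b):
            if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise InvalidGeometryError("electrode directions must be unit 3-vectors")
        if np.allclose(a, b, atol=1e-12):
            raise InvalidGeometryError("electrode directions must differ")
        object.__setattr__(self, "electrode_a", a)
        object.__setattr__(self, "electrode_b", b)


def sphere_potential(
    spec: SphereSpec,
    points: np.ndarray,
    ratio_tol: float = 1e-10,
) -> np.ndarray:
    """Series potential (volts) at world-mm points strictly inside the sphere.

    The Legendre recurrence is accumulated up to ``spec.n_terms`` with early
    stopping once the newest term falls below ``ratio_tol`` of the partial sum
    for two consecutive orders.  If the ratio test never triggers, a
    :class:`TruncationWarning` is emitted.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise EvaluationError("points must be (n, 3) world-mm coordinates")
    r = np.linalg.norm(pts, axis=1)
    if np.any(r >= spec.radius_mm):
        raise EvaluationError("all evaluation points must lie strictly inside the sphere")
    rho = r / spec.radius_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, pts / np.where(r[:, None] > 0, r[:, None], 1.0), 0.0)
    cos_a = unit @ spec.electrode_a
    cos_b = unit @ spec.electrode_b

    # iterative Legendre recurrence for both electrode angles at once
    pa_prev = np.ones_like(cos_a)
    pb_prev = np.ones_like(cos_b)
    pa = cos_a.copy()
    pb = cos_b.copy()
    rho_n = rho.copy()
    total = np.zeros_like(rho)
    converged_streak = 0
    converged = False
    for n in range(1, spec.n_terms + 1):
        term = (2 * n + 1) / n * rho_n * (pa - pb)
        total += term
        scale = np.max(np.abs(total))
        # an identically-zero term (e.g. all points at the origin) counts as
        # converged; otherwise require the ratio test against the partial sum
        if np.max(np.abs(term)) <= ratio_tol * scale:
            converged_streak += 1
            if converged_streak >= 2:
                converged = True
                break
        else:
            converged_streak = 0
        # advance recurrence to order n+1
        pa_next = ((2 * n + 1) * cos_a * pa - n * pa_prev) / (n + 1)
        pb_next = ((2 * n + 1) * cos_b * pb - n * pb_prev) / (n + 1)
        pa_prev, pa = pa, pa_next
        pb_prev, pb = pb, pb_next
        rho_n = rho_n * rho
    if not converged:
        warnings.warn(
            f"series not converged after {spec.n_terms} terms "
            f"(max |rho| = {rho.max():.3f})",
            TruncationWarning,
            stacklevel=2,
        )
    prefactor = (spec.current_mA * 1e-3) / (
        4.0 * np.pi * spec.sigma * spec.radius_mm * 1e-3
    )
    result = prefactor * total
    return result[0] if np.asarray(points).ndim == 1 else result
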