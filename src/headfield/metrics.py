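"""Rotation-invariant lead-field comparison and tES targeting error measures.

Lead fields of different anatomies live in different native frames and are
only comparable up to 3-D rotations, so all comparison measures here are
rotation invariant:

* gain (dB): ``10 log10(||L_ref||_F^2 / ||L_appr||_F^2)`` — relative lead
  field strength; positive gain means the approximate model underestimates
  the field the reference model predicts.
* subspace correlation: ``1 − θ_max/(π/2)`` with θ_max the largest principal
  angle between the column spaces; 1 for subspaces identical up to any
  invertible 3×3 mixing, 0 for orthogonal subspaces; also scale invariant.
* relErr: relative deviation of the achieved field magnitude at a target.
* Jaccard index of the peak-intensity masks (field magnitudes strictly above
  each field's own 75th percentile).
* the global least-squares calibration scalar that brings two lead fields to
  a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError

__all__ = [
    "MetricMap",
    "largest_principal_angle",
    "subspace_correlation",
    "gain_db",
    "calibration_scalar",
    "field_magnitudes",
    "peak_mask",
    "relative_target_error",
    "jaccard_peak",
    "gain_map",
    "subspace_correlation_map",
]

_RANK_RTOL = 1e-12


@dataclass
class MetricMap:
    """Per-cortical-location values of one scalar metric with quartile summary."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D (one scalar per location)")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def q25(self) -> float:
        return float(np.percentile(self.values, 25))

    @property
    def q75(self) -> float:
        return float(np.percentile(self.values, 75))

    def summary(self) -> dict[str, float]:
        return {"median": self.median, "q25": self.q25, "q75": self.q75}


def _orthonormal_basis(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return u[:, :0]
    rank = int(np.sum(s > s[0] * max(a.shape) * _RANK_RTOL))
    return u[:, :rank]


def largest_principal_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle (radians) between the column spaces of a and b.

    Computed from orthonormal bases: the cosines of the principal angles are
    the singular values of Qa^T Qb; the largest angle corresponds to the
    smallest of the min(rank_a, rank_b) singular values.
    """
    qa = _orthonormal_basis(a)
    qb = _orthonormal_basis(b)
    if qa.shape[1] == 0 or qb.shape[1] == 0:
        raise UndefinedMetricError("principal angle undefined for a zero-rank input")
    if qb.shape[1] > qa.shape[1]:
        qa, qb = qb, qa
    # sine route (residual of projecting the smaller basis onto the larger):
    # exact at angle 0, numerically stable for nearly identical subspaces
    residual = qb - qa @ (qa.T @ qb)
    s = np.linalg.svd(residual, compute_uv=False)
    return float(np.arcsin(np.clip(s.max(initial=0.0), 0.0, 1.0)))


def subspace_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """1 − (largest principal angle normalized to [0, 1] by π/2).

    1 means the column spaces coincide (identical lead fields up to any
    invertible linear mixing); 0 means they are orthogonal.
    """
    return 1.0 - largest_principal_angle(a, b) / (np.pi / 2.0)


def gain_db(l_ref: np.ndarray, l_appr: np.ndarray) -> float:
    """Relative lead-field strength in dB; reference in the numerator."""
    l_ref = np.asarray(l_ref, dtype=float)
    l_appr = np.asarray(l_appr, dtype=float)
    if l_ref.shape != l_appr.shape:
        raise UndefinedMetricError("lead-field matrices must have identical shapes")
    denom = np.sum(l_appr**2)
    if denom == 0:
        raise UndefinedMetricError("gain undefined for an all-zero approximate lead field")
    num = np.sum(l_ref**2)
    return float(10.0 * np.log10(num / denom))


def _matched_pairs(l_ref, l_appr, correspondence=None):
    ref = l_ref.matrices if hasattr(l_ref, "matrices") else np.asarray(l_ref, dtype=float)
    appr = l_appr.matrices if hasattr(l_appr, "matrices") else np.asarray(l_appr, dtype=float)
    if correspondence is not None:
        appr = appr[correspondence.appr_indices]
    if ref.shape != appr.shape:
        raise UndefinedMetricError("matched lead fields must have identical shapes")
    return ref, appr


def calibration_scalar(l_ref, l_appr, correspondence=None) -> float:
    """Global scalar α minimising Σ_i ||L_ref_i − α L_appr_i||_F².

    Closed form: α = Σ_i <L_ref_i, L_appr_i>_F / Σ_i ||L_appr_i||_F².
    Accepts :class:`~headfield.solver.LeadField` objects or raw arrays; an
    optional correspondence map aligns approximate to reference locations.
    """
    ref, appr = _matched_pairs(l_ref, l_appr, correspondence)
    denom = np.sum(appr**2)
    if denom == 0:
        raise UndefinedMetricError("calibration undefined for an all-zero lead field")
    return float(np.sum(ref * appr) / denom)


def field_magnitudes(field) -> np.ndarray:
    """Per-location magnitude of an (N, 3) field distribution."""
    f = field.fields if hasattr(field, "fields") else np.asarray(field, dtype=float)
    return np.linalg.norm(np.atleast_2d(f), axis=1)


def peak_mask(values: np.ndarray, percentile: float = 75.0) -> np.ndarray:
    """Boolean mask of values strictly greater than their own percentile
    (linear-interpolation estimator); ties at the threshold are excluded."""
    values = np.asarray(values, dtype=float)
    threshold = np.percentile(values, percentile)
    return values > threshold


def relative_target_error(e_ref, e_appr, target: int) -> float:
    """| |E_appr(r_t)| − |E_ref(r_t)| | / |E_ref(r_t)| at the target location."""
    mag_ref = field_magnitudes(e_ref)[target]
    mag_appr = field_magnitudes(e_appr)[target]
    if mag_ref == 0:
        raise UndefinedMetricError("relErr undefined: zero reference field at target")
    return float(abs(mag_appr - mag_ref) / mag_ref)


def jaccard_peak(e_ref, e_appr, percentile: float = 75.0) -> float:
    """Jaccard overlap of the two fields' peak-intensity masks."""
    mask_ref = peak_mask(field_magnitudes(e_ref), percentile)
    mask_appr = peak_mask(field_magnitudes(e_appr), percentile)
    if mask_ref.shape != mask_appr.shape:
        raise UndefinedMetricError("fields must share the same source space")
    union = np.sum(mask_ref | mask_appr)
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both peak masks are empty")
    return float(np.sum(mask_ref & mask_appr) / union)


def gain_map(l_ref, l_appr, correspondence=None) -> MetricMap:
    """Per-location gain (dB) between matched lead fields."""
    ref, appr = _matched_pairs(l_ref, l_appr, correspondence)
    values = [gain_db(r, a) for r, a in zip(ref, appr)]
    return MetricMap("gain_db", np.array(values))


def subspace_correlation_map(l_ref, l_appr, correspondence=None) -> MetricMap:
    """Per-location subspace correlation between matched lead fields."""
    ref, appr = _matched_pairs(l_ref, l_appr, correspondence)
    values = [subspace_correlation(r, a) for r, a in zip(ref, appr)]
    return MetricMap("subspace_correlation", np.array(values))
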