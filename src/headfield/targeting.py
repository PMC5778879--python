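"""Transcranial electric stimulation (tES) targeting and its evaluation.

Montage optimization: choose per-electrode currents that maximize the
electric field component along the cortical normal at a target location,
subject to the currents summing to zero and the total injected current
(sum of the positive currents, equivalently half the l1 norm) staying
within a safety limit (2 mA by default).  With a linear objective and these
constraints the optimum is attained by a bipolar pair at the limit, which
provides an exhaustive independent oracle for the linear program.

Evaluation: montages optimized in an approximate head model are applied to
the reference model (linear superposition of lead-field rows) and compared
to the reference-optimal field via the relative intensity error at the
target and the Jaccard overlap of the peak-intensity areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .anatomy_map import CorrespondenceMap
from .exceptions import (
    DegenerateObjectiveError,
    MontageCompatibilityError,
    SolverError,
)
from .metrics import (
    MetricMap,
    calibration_scalar,
    jaccard_peak,
    relative_target_error,
)
from .solver import LeadField

__all__ = [
    "Montage",
    "FieldDistribution",
    "optimize_montage",
    "brute_force_bipolar",
    "apply_montage",
    "run_targeting_experiment",
]

_FEAS_TOL = 1e-9


@dataclass
class Montage:
    """Per-electrode injected currents (mA) for one target.

    Invariants: currents sum to zero (the return path is part of the
    montage) and the total injected current — the sum of the positive
    entries — does not exceed the safety limit.
    """

    currents: np.ndarray
    electrode_names: list[str]
    target_index: int
    objective_value: float
    limit_mA: float

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 1 or len(self.currents) != len(self.electrode_names):
            raise MontageCompatibilityError("currents/electrode_names mismatch")
        if abs(self.currents.sum()) > _FEAS_TOL:
            raise SolverError(
                f"montage currents sum to {self.currents.sum():.3e} mA, not zero"
            )
        injected = self.currents[self.currents > 0].sum()
        if injected > self.limit_mA + _FEAS_TOL:
            raise SolverError(
                f"montage injects {injected:.6f} mA above the {self.limit_mA} mA limit"
            )

    @property
    def total_injected_mA(self) -> float:
        return float(self.currents[self.currents > 0].sum())


@dataclass
class FieldDistribution:
    """Electric field 3-vectors (V/m) at every cortical location."""

    fields: np.ndarray
    provenance: dict

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 2 or self.fields.shape[1] != 3:
            raise ValueError("fields must be (N, 3)")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.fields, axis=1)


def _objective_coefficients(leadfield: LeadField, target: int) -> np.ndarray:
    normal = leadfield.source_space.normals[target]
    c = leadfield.matrices[target] @ normal  # per-electrode normal field, V/m per mA
    if np.linalg.norm(c) == 0:
        raise DegenerateObjectiveError(
            "lead field at the target is zero for every electrode"
        )
    return c


def optimize_montage(
    leadfield: LeadField, target: int, limit_mA: float = 2.0
) -> Montage:
    """Maximize the normal-direction field at ``target`` by linear programming.

    Variables are split into positive and negative parts; constraints are
    zero net current and total injected current ≤ ``limit_mA``.  The
    objective value is the achieved normal field in V/m.
    """
    c = _objective_coefficients(leadfield, target)
    m = len(c)
    # minimize -c.(p - q)  s.t.  sum(p) - sum(q) = 0, sum(p) <= limit, sum(q) <= limit
    cost = np.concatenate([-c, c])
    a_eq = np.concatenate([np.ones(m), -np.ones(m)])[None, :]
    a_ub = np.zeros((2, 2 * m))
    a_ub[0, :m] = 1.0
    a_ub[1, m:] = 1.0
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=[limit_mA, limit_mA],
        A_eq=a_eq,
        b_eq=[0.0],
        bounds=(0.0, None),
        method="highs",
    )
    if not res.success:
        raise SolverError(f"montage LP failed: {res.message}")
    currents = res.x[:m] - res.x[m:]
    currents[np.abs(currents) < 1e-12] = 0.0
    return Montage(
        currents=currents,
        electrode_names=list(leadfield.electrode_names),
        target_index=target,
        objective_value=float(c @ currents),
        limit_mA=limit_mA,
    )


def brute_force_bipolar(
    leadfield: LeadField, target: int, limit_mA: float = 2.0
) -> Montage:
    """Exhaustively enumerate all ordered bipolar pairs at ±limit.

    Independent oracle for :func:`optimize_montage`; ties are broken to the
    lowest (source, sink) index pair.
    """
    if leadfield.n_electrodes < 2:
        raise MontageCompatibilityError("need at least 2 electrodes")
    c = _objective_coefficients(leadfield, target)
    m = len(c)
    best = None
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            value = limit_mA * (c[a] - c[b])
            if best is None or value > best[0] + 0.0:
                best = (value, a, b)
    value, a, b = best
    currents = np.zeros(m)
    currents[a] = limit_mA
    currents[b] = -limit_mA
    return Montage(
        currents=currents,
        electrode_names=list(leadfield.electrode_names),
        target_index=target,
        objective_value=float(value),
        limit_mA=limit_mA,
    )


def apply_montage(
    leadfield: LeadField, montage: Montage, calibration: float = 1.0
) -> FieldDistribution:
    """Superpose lead-field rows weighted by the montage currents.

    Electrodes are matched by name; a montage electrode absent from the lead
    field raises :class:`MontageCompatibilityError`.  ``calibration``
    rescales the result when lead fields of different electrical-model
    families are brought to a common scale.
    """
    name_to_col = {name: i for i, name in enumerate(leadfield.electrode_names)}
    weights = np.zeros(leadfield.n_electrodes)
    for name, current in zip(montage.electrode_names, montage.currents):
        if name not in name_to_col:
            if current != 0.0:
                raise MontageCompatibilityError(
                    f"montage electrode {name!r} missing from lead field"
                )
            continue
        weights[name_to_col[name]] = current
    fields = np.einsum("nmc,m->nc", leadfield.matrices, weights) * calibration
    return FieldDistribution(
        fields=fields,
        provenance={
            "target_index": montage.target_index,
            "calibration": calibration,
            "reference_mode": leadfield.reference_mode,
        },
    )


def run_targeting_experiment(
    l_ref: LeadField,
    l_appr: LeadField,
    correspondence: CorrespondenceMap,
    limit_mA: float = 2.0,
    percentile: float = 75.0,
    calibrate: bool = True,
) -> tuple[MetricMap, MetricMap]:
    """Score approximate-model targeting against the reference model.

    For each reference target: optimize a montage in the reference model and
    in the (globally calibrated) approximate model at the matched location,
    apply both montages to the reference model, and compare the resulting
    field distributions by relErr at the target and Jaccard overlap of the
    peak areas.
    """
    if len(correspondence) != l_ref.n_locations:
        raise MontageCompatibilityError(
            "correspondence must cover every reference target"
        )
    alpha = calibration_scalar(l_ref, l_appr, correspondence) if calibrate else 1.0
    l_appr_cal = l_appr.scaled(alpha)
    rel_errors = np.empty(l_ref.n_locations)
    jaccards = np.empty(l_ref.n_locations)
    for i in range(l_ref.n_locations):
        m_ref = optimize_montage(l_ref, i, limit_mA)
        e_ref = apply_montage(l_ref, m_ref)
        j = int(correspondence.appr_indices[i])
        m_appr = optimize_montage(l_appr_cal, j, limit_mA)
        e_appr = apply_montage(l_ref, m_appr)
        rel_errors[i] = relative_target_error(e_ref, e_appr, i)
        jaccards[i] = jaccard_peak(e_ref, e_appr, percentile)
    return MetricMap("rel_err", rel_errors), MetricMap("jaccard", jaccards)
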