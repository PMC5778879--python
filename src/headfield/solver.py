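"""Quasi-static current-flow solver and lead-field assembly.

The head is treated as a volume conductor: injected electrode currents set
up a stationary potential V obeying the current-continuity (Laplace)
equation div(sigma grad V) = 0 with an insulated outer surface.  The voxel
grid is discretized with a 7-point finite-volume stencil: the conductance of
the face between two conducting voxels is the harmonic mean of their
conductivities times face area over voxel pitch, and faces toward air or
background carry zero conductance (insulation).  Current is injected as a
uniform flux over the stimulating electrode's patch voxels; the ground patch
is held at V = 0 (Dirichlet).  The reduced system is symmetric positive
definite and solved with Jacobi-preconditioned conjugate gradients.

Stacking one solve per non-ground electrode and evaluating E = -grad V at
cortical locations yields the lead field: per location an (M, 3) matrix in
V/m per 1 mA injected, which by reciprocity equals the EEG gain matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .exceptions import (
    EvaluationError,
    InvalidSubsetError,
    SolverError,
    TopologyError,
)
from .phantom import (
    CorticalSourceSpace,
    ElectrodeSet,
    TissueConductivityTable,
    VoxelHead,
)

__all__ = [
    "ConductanceSystem",
    "PotentialSolution",
    "LeadField",
    "assemble_system",
    "solve_injection",
    "compute_leadfield",
    "rereference_common_average",
]

DEFAULT_TOL = 1e-8


@dataclass
class ConductanceSystem:
    """Assembled finite-volume operator over the conducting voxels.

    ``node_index`` maps voxel (i,j,k) to a node number (−1 outside the
    conducting region); ``laplacian`` is the symmetric operator with zero row
    sums (interior conservation); conductances are in siemens.
    """

    head: VoxelHead
    sigma_table: TissueConductivityTable
    node_index: np.ndarray
    nodes: np.ndarray
    laplacian: sparse.csr_matrix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_of_voxels(self, voxels: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxels, dtype=int))
        dims = np.asarray(self.head.dims)
        if np.any(v < 0) or np.any(v >= dims):
            raise EvaluationError("voxel outside the grid")
        idx = self.node_index[v[:, 0], v[:, 1], v[:, 2]]
        if np.any(idx < 0):
            raise EvaluationError("voxel outside the conducting region")
        return idx


@dataclass
class PotentialSolution:
    """Potential (volts) at every conducting node for one bipolar injection."""

    potentials: np.ndarray
    injected_electrode: int
    residual: float
    net_current_mA: float
    system: ConductanceSystem

    def potential_grid(self) -> np.ndarray:
        """Potential on the full voxel grid (NaN outside the conductor)."""
        grid = np.full(self.system.head.dims, np.nan)
        nodes = self.system.nodes
        grid[nodes[:, 0], nodes[:, 1], nodes[:, 2]] = self.potentials
        return grid


@dataclass
class LeadField:
    """Per-location (M, 3) lead-field matrices, V/m per 1 mA injected.

    ``matrices`` has shape (N, M, 3): N cortical locations, M electrodes,
    3 field components.  ``reference_mode`` is ``"ground"`` (the ground
    electrode's row is identically zero) or ``"common_average"`` (each
    column sums to zero across electrodes).
    """

    matrices: np.ndarray
    electrode_names: list[str]
    source_space: CorticalSourceSpace
    reference_mode: str = "ground"
    ground_index: int | None = None
    units: str = "V/m per mA"

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[2] != 3:
            raise ValueError("matrices must have shape (N, M, 3)")
        if self.matrices.shape[1] != len(self.electrode_names):
            raise ValueError("electrode count mismatch")
        if self.matrices.shape[0] != len(self.source_space):
            raise ValueError("source-space size mismatch")

    @property
    def n_locations(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.matrices.shape[1]

    def scaled(self, factor: float) -> "LeadField":
        return replace(self, matrices=self.matrices * factor)


def assemble_system(
    head: VoxelHead, sigma: TissueConductivityTable
) -> ConductanceSystem:
    """Build the 7-point finite-volume operator for a head.

    Face conductance between conducting voxels = harmonic mean of the two
    conductivities × face area / pitch; with isotropic voxels of edge h this
    reduces to sigma_harmonic · h (in metres).  A conducting region that is
    not a single 6-connected component raises :class:`TopologyError`.
    """
    sig = sigma.grid(head.labels)
    mask = head.conducting_mask & (sig > 0)
    if not mask.any():
        raise TopologyError("head has no conducting voxels with positive conductivity")
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(3, 1)
    _, n_comp = ndimage.label(mask, structure=structure)
    if n_comp != 1:
        raise TopologyError(
            f"conducting region has {n_comp} components; the grounded system "
            "would be singular"
        )

    node_index = np.full(head.dims, -1, dtype=np.int64)
    nodes = np.argwhere(mask)
    node_index[mask] = np.arange(len(nodes))

    h_m = head.voxel_size * 1e-3  # face area / pitch = h (isotropic voxels)
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s1 = sig[tuple(sl_lo)]
        s2 = sig[tuple(sl_hi)]
        both = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        g = np.zeros_like(s1)
        np.divide(2.0 * s1 * s2, s1 + s2, out=g, where=both)
        g *= h_m
        i1 = node_index[tuple(sl_lo)][both]
        i2 = node_index[tuple(sl_hi)][both]
        gv = g[both]
        rows.extend([i1, i2, i1, i2])
        cols.extend([i2, i1, i1, i2])
        vals.extend([-gv, -gv, gv, gv])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    lap = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes))
    ).tocsr()
    return ConductanceSystem(
        head=head, sigma_table=sigma, node_index=node_index,
        nodes=nodes, laplacian=lap,
    )


def solve_injection(
    system: ConductanceSystem,
    electrodes: ElectrodeSet,
    stim_index: int,
    total_current_mA: float = 1.0,
    tol: float = DEFAULT_TOL,
) -> PotentialSolution:
    """Solve one bipolar injection: ``total_current_mA`` spread uniformly over
    the stimulating electrode's patch, ground patch held at V = 0.

    Converges to relative residual ``tol`` with conjugate gradients (Jacobi
    preconditioning, iteration cap 100·sqrt(unknowns)); non-convergence
    raises :class:`SolverError` carrying the achieved residual.
    """
    if stim_index == electrodes.ground_index:
        raise SolverError("stimulation electrode must differ from ground")
    stim_nodes = system.node_of_voxels(electrodes.patch_voxels[stim_index])
    ground_nodes = system.node_of_voxels(electrodes.patch_voxels[electrodes.ground_index])

    n = system.n_nodes
    current_A = total_current_mA * 1e-3
    b = np.zeros(n)
    b[stim_nodes] = current_A / len(stim_nodes)

    free = np.ones(n, dtype=bool)
    free[ground_nodes] = False
    free_idx = np.flatnonzero(free)
    a_ff = system.laplacian[free_idx][:, free_idx].tocsr()
    b_f = b[free_idx]

    diag = a_ff.diagonal()
    inv_diag = np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), 1.0)
    precond = LinearOperator(a_ff.shape, matvec=lambda x: inv_diag * x)
    maxiter = int(100 * np.sqrt(len(free_idx))) + 100
    x, info = cg(a_ff, b_f, rtol=tol, atol=0.0, maxiter=maxiter, M=precond)
    residual = float(np.linalg.norm(a_ff @ x - b_f) / np.linalg.norm(b_f))
    if info != 0:
        raise SolverError(
            f"conjugate gradients did not converge (info={info})", residual=residual
        )

    v_full = np.zeros(n)
    v_full[free_idx] = x
    nodal = system.laplacian @ v_full  # external current entering each node
    net_mA = float(nodal[stim_nodes].sum() * 1e3)
    return PotentialSolution(
        potentials=v_full,
        injected_electrode=stim_index,
        residual=residual,
        net_current_mA=net_mA,
        system=system,
    )


def _field_at_voxels(system: ConductanceSystem, grid: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """E = -grad V (V/m) at voxel centres by central differences.

    Falls back to one-sided differences where a neighbour is non-conducting;
    a voxel with no conducting neighbour along some axis raises
    :class:`EvaluationError`.
    """
    h_m = system.head.voxel_size * 1e-3
    dims = system.head.dims
    vox = np.atleast_2d(np.asarray(voxels, dtype=int))
    field = np.empty((len(vox), 3))
    conducting = system.node_index >= 0
    v_here = grid[vox[:, 0], vox[:, 1], vox[:, 2]]
    for axis in range(3):
        plus = vox.copy()
        minus = vox.copy()
        plus[:, axis] += 1
        minus[:, axis] -= 1
        ok_plus = (plus[:, axis] < dims[axis])
        ok_minus = (minus[:, axis] >= 0)
        ok_plus &= conducting[plus[:, 0] % dims[0], plus[:, 1] % dims[1], plus[:, 2] % dims[2]] & (plus[:, axis] < dims[axis])
        ok_minus &= conducting[minus[:, 0] % dims[0], minus[:, 1] % dims[1], minus[:, 2] % dims[2]] & (minus[:, axis] >= 0)
        v_plus = np.where(ok_plus, grid[plus[:, 0] % dims[0], plus[:, 1] % dims[1], plus[:, 2] % dims[2]], 0.0)
        v_minus = np.where(ok_minus, grid[minus[:, 0] % dims[0], minus[:, 1] % dims[1], minus[:, 2] % dims[2]], 0.0)
        grad = np.empty(len(vox))
        both = ok_plus & ok_minus
        only_plus = ok_plus & ~ok_minus
        only_minus = ok_minus & ~ok_plus
        neither = ~ok_plus & ~ok_minus
        if np.any(neither):
            raise EvaluationError(
                "source voxel has no conducting neighbour along an axis"
            )
        grad[both] = (v_plus[both] - v_minus[both]) / (2.0 * h_m)
        grad[only_plus] = (v_plus[only_plus] - v_here[only_plus]) / h_m
        grad[only_minus] = (v_here[only_minus] - v_minus[only_minus]) / h_m
        field[:, axis] = -grad
    return field


def compute_leadfield(
    head: VoxelHead,
    sigma: TissueConductivityTable,
    electrodes: ElectrodeSet,
    sources: CorticalSourceSpace,
    total_current_mA: float = 1.0,
    tol: float = DEFAULT_TOL,
) -> LeadField:
    """Solve every electrode against ground and stack the brain electric
    fields at the cortical source locations into a ground-referenced lead
    field (the ground electrode's row is identically zero)."""
    system = assemble_system(head, sigma)
    if sources.voxel_indices is not None:
        voxels = np.asarray(sources.voxel_indices, dtype=int)
    else:
        voxels = np.rint(head.world_to_voxel(sources.locations)).astype(int)
    # validate that every source voxel is conducting
    system.node_of_voxels(voxels)

    n_loc = len(sources)
    m = electrodes.n
    matrices = np.zeros((n_loc, m, 3))
    for e in range(m):
        if e == electrodes.ground_index:
            continue
        sol = solve_injection(system, electrodes, e, total_current_mA, tol)
        matrices[:, e, :] = _field_at_voxels(system, sol.potential_grid(), voxels)
    if total_current_mA != 1.0:
        matrices /= total_current_mA  # report per 1 mA
    return LeadField(
        matrices=matrices,
        electrode_names=list(electrodes.names),
        source_space=sources,
        reference_mode="ground",
        ground_index=electrodes.ground_index,
    )


def rereference_common_average(
    leadfield: LeadField, subset: np.ndarray | list[int] | None = None
) -> LeadField:
    """Restrict to an electrode subset and subtract the per-column mean.

    After the operation every column of every per-location matrix sums to
    zero across the retained electrodes; applying it twice is idempotent.
    """
    if subset is None:
        subset = np.arange(leadfield.n_electrodes)
    subset = np.asarray(subset, dtype=int)
    if subset.ndim != 1 or len(subset) < 2:
        raise InvalidSubsetError("subset must contain at least 2 electrodes")
    if len(np.unique(subset)) != len(subset):
        raise InvalidSubsetError("subset contains duplicate electrodes")
    if subset.min() < 0 or subset.max() >= leadfield.n_electrodes:
        raise InvalidSubsetError("subset references unknown electrodes")
    sub = leadfield.matrices[:, subset, :]
    sub = sub - sub.mean(axis=1, keepdims=True)
    return LeadField(
        matrices=sub,
        electrode_names=[leadfield.electrode_names[i] for i in subset],
        source_space=leadfield.source_space,
        reference_mode="common_average",
        ground_index=None,
    )
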