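"""Synthetic multi-tissue voxel heads with known ground truth.

Concentric-shell sphere phantoms stand in for segmented MRI heads: nested
scalp/skull/CSF/gray-matter/white-matter shells on an isotropic voxel grid,
optionally with a carved air pocket inside the skull.  Affinely perturbed
copies emulate distinct individual anatomies with an exactly known
anatomy-to-anatomy transform, which downstream correspondence and
localization experiments can use as ground truth.

Tissue label codes: 0 background, 1 scalp, 2 skull, 3 CSF, 4 gray matter,
5 white matter, 6 air.  World coordinates are mm; the voxel-index-to-world
map is a standard 4x4 affine with the head centred at the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .anatomy_map import AffineTransform
from .exceptions import (
    BoundsError,
    CapacityError,
    InvalidGeometryError,
    InvalidTransformError,
    PlacementError,
)

__all__ = [
    "BACKGROUND", "SCALP", "SKULL", "CSF", "GM", "WM", "AIR",
    "CONDUCTING_LABELS", "TISSUE_NAMES",
    "VoxelHead", "TissueConductivityTable", "ElectrodeSet", "CorticalSourceSpace",
    "make_sphere_head", "perturb_anatomy", "place_electrodes", "extract_source_space",
]

BACKGROUND, SCALP, SKULL, CSF, GM, WM, AIR = 0, 1, 2, 3, 4, 5, 6
CONDUCTING_LABELS = (SCALP, SKULL, CSF, GM, WM)
TISSUE_NAMES = {
    BACKGROUND: "background", SCALP: "scalp", SKULL: "skull",
    CSF: "csf", GM: "gm", WM: "wm", AIR: "air",
}
_NAME_TO_CODE = {v: k for k, v in TISSUE_NAMES.items()}

# translation drawn per component from U(-1, 1) * magnitude * this scale (mm),
# so magnitude 0.02-0.10 gives millimetre-scale shifts comparable to the
# shape perturbation of a head-sized sphere
_TRANSLATION_SCALE_MM = 50.0


@dataclass
class VoxelHead:
    """Labeled 3-D tissue grid plus voxel-index-to-world-mm affine."""

    labels: np.ndarray
    voxel_size: float
    affine: np.ndarray
    generating_transform: AffineTransform | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidGeometryError("labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidGeometryError("labels must be integer-valued")
        if self.voxel_size <= 0:
            raise InvalidGeometryError("voxel_size must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise InvalidGeometryError("affine must be 4x4")
        valid = set(TISSUE_NAMES)
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise InvalidGeometryError(f"invalid tissue codes {sorted(present - valid)}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_to_world(self, indices) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if np.asarray(indices).ndim == 1 else out

    def world_to_voxel(self, points) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = p @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.isin(self.labels, CONDUCTING_LABELS)

    def conducting_component_count(self) -> int:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        _, n = ndimage.label(self.conducting_mask, structure=structure)
        return int(n)


@dataclass(frozen=True)
class TissueConductivityTable:
    """Map tissue code -> conductivity in S/m; air and background conduct nothing."""

    sigma: Mapping[int, float]

    def __post_init__(self):
        s = dict(self.sigma)
        for code in CONDUCTING_LABELS:
            if code in s and s[code] <= 0:
                raise InvalidGeometryError(
                    f"conductivity for {TISSUE_NAMES[code]} must be > 0"
                )
        for code in (BACKGROUND, AIR):
            if s.get(code, 0.0) != 0.0:
                raise InvalidGeometryError(
                    f"{TISSUE_NAMES[code]} must be non-conducting"
                )
            s[code] = 0.0
        object.__setattr__(self, "sigma", s)

    @classmethod
    def three_shell(cls) -> "TissueConductivityTable":
        """Classic three-compartment values: brain-side tissues and scalp at
        0.33 S/m, skull at 0.041 S/m.  Per-tissue refinements (e.g. a distinct
        CSF value) are user-supplied."""
        return cls({SCALP: 0.33, SKULL: 0.041, CSF: 0.33, GM: 0.33, WM: 0.33})

    @classmethod
    def uniform(cls, sigma: float = 0.33) -> "TissueConductivityTable":
        """All conducting tissues at one value; used for analytic-oracle checks."""
        return cls({code: sigma for code in CONDUCTING_LABELS})

    @classmethod
    def from_named(cls, named: Mapping[str, float]) -> "TissueConductivityTable":
        return cls({_NAME_TO_CODE[k.lower()]: v for k, v in named.items()})

    def as_named(self) -> dict[str, float]:
        return {TISSUE_NAMES[k]: v for k, v in sorted(self.sigma.items())}

    def grid(self, labels: np.ndarray) -> np.ndarray:
        """Per-voxel conductivity grid (0 for tissues absent from the table)."""
        lut = np.zeros(max(TISSUE_NAMES) + 1)
        for code, value in self.sigma.items():
            lut[code] = value
        return lut[labels]


@dataclass
class ElectrodeSet:
    """Named scalp electrodes with their current-carrying surface voxel patches."""

    names: list[str]
    positions: np.ndarray
    patch_voxels: list[np.ndarray]
    ground_index: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) < 2:
            raise PlacementError("need at least 2 electrodes")
        if len(self.names) != len(self.positions) or len(self.names) != len(self.patch_voxels):
            raise PlacementError("names/positions/patches length mismatch")
        if not 0 <= self.ground_index < len(self.names):
            raise PlacementError("ground_index out of range")
        seen: set[tuple[int, int, int]] = set()
        for patch in self.patch_voxels:
            for vox in np.atleast_2d(patch):
                key = tuple(int(v) for v in vox)
                if key in seen:
                    raise PlacementError("electrode patches overlap")
                seen.add(key)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def ground_name(self) -> str:
        return self.names[self.ground_index]


@dataclass
class CorticalSourceSpace:
    """Cortical sample locations (world mm) with outward unit normals."""

    locations: np.ndarray
    normals: np.ndarray
    voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        self.locations = np.asarray(self.locations, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.locations.shape != self.normals.shape or self.locations.ndim != 2:
            raise InvalidGeometryError("locations and normals must be matching (N, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidGeometryError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.locations)


def _centered_affine(dims: Sequence[int], voxel_size: float) -> np.ndarray:
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(dims) - 1) / 2.0
    return affine


def _radius_grid(dims, affine) -> np.ndarray:
    idx = np.indices(dims).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    return np.linalg.norm(world, axis=1).reshape(dims)


def make_sphere_head(
    radii: Sequence[float],
    voxel_size: float,
    air_pocket: tuple[Sequence[float], float] | None = None,
    dims: Sequence[int] | None = None,
) -> VoxelHead:
    """Concentric-shell sphere phantom.

    ``radii`` are the outer radii (mm, strictly decreasing) of scalp, skull,
    CSF, gray matter and white matter.  Each voxel is labeled by the distance
    of its centre from the head origin (no partial-volume handling).
    ``air_pocket = (center_mm, radius_mm)`` carves a spherical air cavity out
    of skull voxels.  ``dims`` overrides the automatic grid size; a grid too
    small to hold the outer sphere plus a 1-voxel background margin raises
    :class:`BoundsError`.
    """
    radii = [float(r) for r in radii]
    if len(radii) != 5:
        raise InvalidGeometryError("expected 5 radii (scalp, skull, CSF, GM, WM)")
    if any(r <= 0 for r in radii) or any(a <= b for a, b in zip(radii, radii[1:])):
        raise InvalidGeometryError("radii must be positive and strictly decreasing")
    if voxel_size <= 0:
        raise InvalidGeometryError("voxel_size must be positive")
    outer = radii[0]
    if dims is None:
        half = int(np.ceil(outer / voxel_size)) + 1
        dims = (2 * half + 1,) * 3
    else:
        dims = tuple(int(d) for d in dims)
        half_extent = voxel_size * (min(dims) - 1) / 2.0
        if half_extent < outer + voxel_size:
            raise BoundsError(
                f"grid of dims {dims} at {voxel_size} mm cannot hold radius "
                f"{outer} mm plus a 1-voxel margin"
            )
    affine = _centered_affine(dims, voxel_size)
    r = _radius_grid(dims, affine)
    labels = np.zeros(dims, dtype=np.int16)
    for code, radius in zip((SCALP, SKULL, CSF, GM, WM), radii):
        labels[r <= radius] = code
    if air_pocket is not None:
        center, pocket_radius = air_pocket
        center = np.asarray(center, dtype=float)
        if pocket_radius <= 0:
            raise InvalidGeometryError("air pocket radius must be positive")
        idx = np.indices(dims).reshape(3, -1).T.astype(float)
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        inside = (np.linalg.norm(world - center, axis=1) <= pocket_radius).reshape(dims)
        labels[inside & (labels == SKULL)] = AIR
    return VoxelHead(labels=labels, voxel_size=voxel_size, affine=affine)


def random_affine(seed: int, magnitude: float) -> AffineTransform:
    """Seeded random 12-parameter affine with scale/shear deviations bounded
    by ``magnitude`` and millimetre-scale translation (see module notes)."""
    if magnitude < 0:
        raise InvalidTransformError("magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    linear = np.eye(3) + rng.uniform(-magnitude, magnitude, size=(3, 3))
    translation = rng.uniform(-1.0, 1.0, size=3) * magnitude * _TRANSLATION_SCALE_MM
    if np.linalg.det(linear) <= 0:
        raise InvalidTransformError(
            "sampled affine has non-positive determinant; reduce magnitude"
        )
    return AffineTransform.from_linear(linear, translation, kind="affine12")


def perturb_anatomy(
    head: VoxelHead,
    affine: AffineTransform | np.ndarray | None = None,
    seed: int | None = None,
    magnitude: float | None = None,
) -> tuple[VoxelHead, AffineTransform]:
    """Resample a head under an affine anatomy perturbation.

    Either pass an explicit ``affine`` (world-mm, applied to the anatomy) or
    ``seed`` and ``magnitude`` to draw a random one.  Labels are resampled
    with nearest-neighbour interpolation onto a grid large enough to contain
    the transformed head; the exact transform used is returned and also
    composed into the output head's ``generating_transform`` so that
    ground-truth correspondence and normals remain available.
    """
    if affine is None:
        if seed is None or magnitude is None:
            raise InvalidTransformError("need either an affine or (seed, magnitude)")
        transform = random_affine(seed, magnitude)
    elif isinstance(affine, AffineTransform):
        transform = affine
    else:
        transform = AffineTransform(np.asarray(affine, dtype=float))
    if np.linalg.det(transform.linear) <= 0:
        raise InvalidTransformError("anatomy transform must preserve orientation")

    dims_in = np.asarray(head.dims)
    corners_idx = np.array(
        [[i, j, k] for i in (0, dims_in[0] - 1)
         for j in (0, dims_in[1] - 1)
         for k in (0, dims_in[2] - 1)], dtype=float)
    corners_world = transform.apply(head.voxel_to_world(corners_idx))
    extent = np.abs(corners_world).max()
    half = int(np.ceil(extent / head.voxel_size)) + 1
    dims_out = (2 * half + 1,) * 3
    affine_out = _centered_affine(dims_out, head.voxel_size)

    # output index -> output world -> inverse anatomy transform -> input index
    inv = transform.inverse()
    idx_out = np.indices(dims_out).reshape(3, -1).T.astype(float)
    world_out = idx_out @ affine_out[:3, :3].T + affine_out[:3, 3]
    world_in = inv.apply(world_out)
    inv_head = np.linalg.inv(head.affine)
    idx_in = world_in @ inv_head[:3, :3].T + inv_head[:3, 3]
    labels_out = ndimage.map_coordinates(
        head.labels, idx_in.T, order=0, mode="constant", cval=BACKGROUND
    ).reshape(dims_out)

    # nearest-neighbour resampling under shear can strand isolated conducting
    # voxels at the surface; keep the largest 6-connected conducting component
    # (the same cleanup segmentation pipelines apply to disconnected regions)
    conducting = np.isin(labels_out, CONDUCTING_LABELS)
    structure = ndimage.generate_binary_structure(3, 1)
    components, n_comp = ndimage.label(conducting, structure=structure)
    if n_comp > 1:
        sizes = ndimage.sum_labels(conducting, components, index=np.arange(1, n_comp + 1))
        keep = 1 + int(np.argmax(sizes))
        labels_out[conducting & (components != keep)] = BACKGROUND

    total = transform if head.generating_transform is None \
        else transform.compose(head.generating_transform)
    out = VoxelHead(
        labels=labels_out.astype(head.labels.dtype),
        voxel_size=head.voxel_size,
        affine=affine_out,
        generating_transform=total,
    )
    return out, transform


def _scalp_surface_voxels(head: VoxelHead) -> np.ndarray:
    """Scalp voxels with at least one 6-neighbour outside the conducting head."""
    scalp = head.labels == SCALP
    exposed = np.zeros_like(scalp)
    nonconducting = ~head.conducting_mask
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(nonconducting, shift, axis=axis)
            # rolled-in face voxels border the grid edge: treat as exposed
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            neighbor[tuple(edge)] = True
            exposed |= scalp & neighbor
    return np.argwhere(exposed)


def fibonacci_directions(m: int, coverage_deg: float) -> np.ndarray:
    """Deterministic near-uniform unit directions within a polar cap.

    Polar angle (from +z) spans the cap of half-angle ``coverage_deg``;
    azimuth advances by the golden angle.  Directions are ordered by
    increasing polar angle, so the last one is the most 'inferior'.
    """
    if m < 2:
        raise PlacementError("need at least 2 electrodes")
    if not 0.0 < coverage_deg <= 180.0:
        raise PlacementError("coverage must be in (0, 180] degrees")
    i = np.arange(m)
    u = 1.0 - (1.0 - np.cos(np.deg2rad(coverage_deg))) * (i + 0.5) / m
    theta = np.arccos(np.clip(u, -1.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    return np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def place_electrodes(
    head: VoxelHead,
    m: int,
    coverage_deg: float = 180.0,
    ground_name: str = "Iz",
) -> ElectrodeSet:
    """Place ``m`` electrodes on the scalp surface of a phantom.

    Ideal directions follow a deterministic spherical-spiral (Fibonacci)
    layout within the polar cap of half-angle ``coverage_deg``; each is
    snapped to the best-aligned exposed scalp-surface voxel.  The electrode
    with the largest polar angle plays the role of the inferior ground
    electrode and receives ``ground_name``.  Overlapping patches (too many
    electrodes for the available surface) raise :class:`PlacementError`.
    """
    directions = fibonacci_directions(m, coverage_deg)
    surface = _scalp_surface_voxels(head)
    if len(surface) == 0:
        raise PlacementError("head has no exposed scalp surface")
    surf_world = head.voxel_to_world(surface.astype(float))
    norms = np.linalg.norm(surf_world, axis=1)
    if np.any(norms == 0):
        raise PlacementError("scalp surface voxel at the origin")
    surf_unit = surf_world / norms[:, None]
    chosen = np.argmax(surf_unit @ directions.T, axis=0)
    if len(set(chosen.tolist())) != m:
        raise PlacementError(
            f"{m} electrodes do not fit disjointly on this scalp surface"
        )
    names = [f"E{i:03d}" for i in range(m)]
    ground_index = m - 1  # largest polar angle by construction
    names[ground_index] = ground_name
    positions = surf_world[chosen]
    patches = [surface[c][None, :].copy() for c in chosen]
    return ElectrodeSet(
        names=names, positions=positions, patch_voxels=patches,
        ground_index=ground_index,
    )


def extract_source_space(head: VoxelHead, n: int) -> CorticalSourceSpace:
    """Deterministically subsample ``n`` gray-matter voxels as cortical sources.

    Voxels are taken with a uniform stride over the sorted flat GM voxel
    indices.  Normals are the outward radial directions of the generating
    sphere, pushed through the head's generating affine by the
    inverse-transpose rule and re-normalised (exact for level-set surfaces).
    """
    gm = np.argwhere(head.labels == GM)
    count = len(gm)
    if count == 0:
        raise CapacityError("head contains no gray-matter voxels")
    if n > count:
        raise CapacityError(f"requested {n} sources but only {count} GM voxels")
    sel = np.array([i * count // n for i in range(n)], dtype=int)
    voxels = gm[sel]
    locations = head.voxel_to_world(voxels.astype(float))
    transform = head.generating_transform
    if transform is None:
        radial = locations
    else:
        radial = transform.inverse().apply(locations)
    rnorm = np.linalg.norm(radial, axis=1)
    if np.any(rnorm == 0):
        raise InvalidGeometryError("gray-matter voxel at the head origin")
    n0 = radial / rnorm[:, None]
    if transform is None:
        normals = n0
    else:
        normals = n0 @ np.linalg.inv(transform.linear)  # n0 @ A^-1 == (A^-T n0)^T
        normals /= np.linalg.norm(normals, axis=1)[:, None]
    return CorticalSourceSpace(locations=locations, normals=normals, voxel_indices=voxels)
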