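"""Voxel-volume machinery for drilling-outcome evaluation.

The universal representation is a :class:`VoxelGrid` — a 3D boolean occupancy
mask with physical spacing and origin, where ``True`` means material present
(undrilled).  Tooth phantoms are described by labelled sphere sets and turned
into occupancy masks either as a hard union of balls or as a summed compactly
supported metaball field.  An actual drilling outcome is compared against the
ideal outcome voxel-by-voxel inside the initial tooth region, yielding the
TP/TN/FP/FN tallies that all downstream scores are built from.

Voxel convention (used everywhere in this package): 0-based indices,
voxel-center sampling, world position of voxel ``(i, j, k)`` =
``origin + (i, j, k) * spacing``.  All physical quantities are centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
import trimesh

__all__ = [
    "DEFAULT_SHAPE",
    "VoxelGrid",
    "SphereSet",
    "ClassificationCounts",
    "occupancy_from_spheres",
    "extract_surface_mesh",
    "classify_outcome",
]

#: Default discretization resolution of the tooth region.
DEFAULT_SHAPE = (90, 135, 90)

TISSUES = ("enamel", "dentin", "pulp")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class VoxelGrid:
    """3D boolean occupancy mask with physical placement.

    Parameters
    ----------
    mask : ndarray of bool, shape (nx, ny, nz)
        ``True`` = material present (undrilled).
    spacing : triple of float
        Physical size of one voxel along each axis, cm.
    origin : triple of float
        World position (cm) of the *center* of voxel (0, 0, 0).
    """

    mask: np.ndarray
    spacing: tuple[float, float, float] = (0.015, 0.015, 0.015)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if mask.ndim != 3 or any(n < 1 for n in mask.shape):
            raise ValidationError(f"mask must be 3D with positive shape, got {mask.shape}")
        if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive reals, got {spacing}")
        if len(origin) != 3 or any(not np.isfinite(o) for o in origin):
            raise ValidationError(f"origin must be three finite reals, got {origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in cm^3."""
        return float(np.prod(self.spacing))

    def count(self) -> int:
        """Number of occupied voxels."""
        return int(self.mask.sum())

    def volume(self) -> float:
        """Occupied volume in cm^3."""
        return self.count() * self.voxel_volume

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_mask(self, mask: np.ndarray) -> "VoxelGrid":
        """New grid on the same lattice with a different mask."""
        return VoxelGrid(mask, self.spacing, self.origin)

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (cm) of voxel centers for an (n, 3) index array."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)


@dataclass(frozen=True)
class SphereSet:
    """Labelled spheres defining a tooth phantom as an implicit field.

    ``labels`` tag each sphere with a tissue from ``{"enamel", "dentin", "pulp"}``.
    """

    centers: np.ndarray  # (n, 3) cm
    radii: np.ndarray  # (n,) cm, > 0
    labels: np.ndarray = field(default=None)  # (n,) str

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 3)
        if self.labels is None:
            labels = np.full(len(radii), "dentin", dtype=object)
        else:
            labels = np.atleast_1d(np.asarray(self.labels, dtype=object))
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "labels", labels)
        if centers.shape != (len(radii), 3) or len(labels) != len(radii):
            raise ValidationError(
                f"inconsistent lengths: centers {centers.shape}, radii {radii.shape}, labels {labels.shape}"
            )
        if len(radii) and (not np.all(np.isfinite(centers)) or not np.all(np.isfinite(radii))):
            raise ValidationError("sphere centers and radii must be finite")
        if len(radii) and not np.all(radii > 0):
            raise ValidationError("sphere radii must be positive")
        bad = set(labels) - set(TISSUES)
        if bad:
            raise ValidationError(f"unknown tissue labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.radii)

    def subset(self, tissue: str) -> "SphereSet":
        sel = self.labels == tissue
        return SphereSet(self.centers[sel], self.radii[sel], self.labels[sel])

    @staticmethod
    def concatenate(parts: list["SphereSet"]) -> "SphereSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return SphereSet(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=object))
        return SphereSet(
            np.concatenate([p.centers for p in parts]),
            np.concatenate([p.radii for p in parts]),
            np.concatenate([p.labels for p in parts]),
        )


@dataclass(frozen=True)
class ClassificationCounts:
    """TP/TN/FP/FN voxel tallies from comparing actual vs ideal outcome.

    Semantics (positive class = undrilled/material present):

    * TP — correctly undrilled voxels
    * TN — correctly drilled voxels
    * FP — incorrectly undrilled voxels (under-drilling)
    * FN — incorrectly drilled voxels (over-drilling)

    ``TP + TN + FP + FN`` equals the voxel count of the initial tooth mask.
    """

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


# ---------------------------------------------------------------------------
# occupancy from spheres


def _field_grid_axes(shape, spacing, origin):
    return [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]


def occupancy_from_spheres(
    spheres: SphereSet,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = (0.015, 0.015, 0.015),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    kernel: str = "boolean",
    threshold: float = 1.0,
    support_scale: float = 1.5,
) -> VoxelGrid:
    """Discretize a sphere set into a boolean occupancy mask.

    Two kernels are offered:

    ``"boolean"``
        Hard union of balls: a voxel center is occupied iff it lies inside at
        least one sphere.  Equivalent to a max-style field thresholded at the
        sphere boundary; exact and used by the synthesis module.
    ``"metaball"``
        Smooth blending: each sphere contributes a compactly supported
        polynomial falloff ``((1 - (d/R)^2) / (1 - (r/R)^2))^3`` for
        ``d <= R = support_scale * r``, normalized so the single-sphere field
        equals 1 exactly at the nominal boundary ``d = r``.  Contributions are
        summed over spheres and the mask is ``field >= threshold``
        (default 1), so overlapping spheres fuse smoothly.

    An empty sphere set yields a valid all-false mask.
    """
    if kernel not in ("boolean", "metaball"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if not (np.isfinite(threshold) and threshold > 0):
        raise ValidationError("threshold must be positive and finite")
    mask_or_field = (
        np.zeros(shape, dtype=bool) if kernel == "boolean" else np.zeros(shape, dtype=np.float64)
    )
    if len(spheres) == 0:
        return VoxelGrid(np.zeros(shape, dtype=bool), spacing, origin)

    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    for c, r in zip(spheres.centers, spheres.radii):
        reach = r if kernel == "boolean" else support_scale * r
        # local bounding box of the sphere's support (voxel-center sampling)
        lo = [max(0, int(np.ceil((c[a] - reach - origin[a]) / spacing[a]))) for a in range(3)]
        hi = [min(shape[a], int(np.floor((c[a] + reach - origin[a]) / spacing[a])) + 1) for a in range(3)]
        if any(lo[a] >= hi[a] for a in range(3)):
            continue
        ax = [
            origin[a] + spacing[a] * np.arange(lo[a], hi[a]) - c[a]
            for a in range(3)
        ]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        if kernel == "boolean":
            mask_or_field[sub] |= d2 <= r * r
        else:
            R2 = reach * reach
            norm = (1.0 - (r * r) / R2) ** 3
            contrib = np.clip(1.0 - d2 / R2, 0.0, None) ** 3 / norm
            mask_or_field[sub] += contrib
    mask = mask_or_field if kernel == "boolean" else mask_or_field >= threshold
    return VoxelGrid(mask, spacing, origin)


# ---------------------------------------------------------------------------
# surface extraction


def signed_distance_field(grid: VoxelGrid) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive outside, in cm.

    Isotropic only in physical units; uses the sampling spacing of the grid.
    """
    inside = ndimage.distance_transform_edt(grid.mask, sampling=grid.spacing)
    outside = ndimage.distance_transform_edt(~grid.mask, sampling=grid.spacing)
    return outside - inside


def extract_surface_mesh(
    grid: VoxelGrid, method: str = "smooth", smoothing_voxels: float = 0.8
) -> trimesh.Trimesh:
    """Extract a closed, consistently oriented triangle surface of the mask.

    The iso-surface is the 0.5 level separating occupied from empty voxels.
    By default the binary field is first smoothed with a narrow Gaussian
    (``smoothing_voxels`` standard deviations in voxel units) so marching
    cubes recovers the surface with sub-voxel accuracy instead of the raw
    staircase; ``method="binary"`` runs directly on the 0/1 field.  Vertex
    coordinates are world cm.

    An all-false or all-true mask has no iso-surface and yields an empty mesh
    (``mesh.is_empty``), which callers must check.
    """
    mask = grid.mask
    if not mask.any() or mask.all():
        return trimesh.Trimesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int))
    # pad so islands touching the array border still close
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    origin = tuple(o - s for o, s in zip(grid.origin, grid.spacing))
    if method == "smooth":
        field = ndimage.gaussian_filter(padded.astype(np.float64), smoothing_voxels)
        if field.max() <= 0.5 or field.min() >= 0.5:
            # features thinner than the smoothing kernel: keep the raw field
            field = padded.astype(np.float64)
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=grid.spacing)
    elif method == "binary":
        verts, faces, _, _ = measure.marching_cubes(
            padded.astype(np.float32), level=0.5, spacing=grid.spacing
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    verts = verts + np.asarray(origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # enforce outward orientation
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# outcome classification


def classify_outcome(initial: VoxelGrid, ideal: VoxelGrid, actual: VoxelGrid) -> ClassificationCounts:
    """Classify an actual drilling outcome against the ideal one, voxel-wise.

    The classification domain is the initial tooth mask: voxels that were
    never part of the tooth are ignored.  Within it, with "positive" =
    material present (undrilled):

    * TP: present in actual and in ideal (correctly undrilled)
    * TN: absent in actual and in ideal (correctly drilled)
    * FP: present in actual, absent in ideal (under-drilling)
    * FN: absent in actual, present in ideal (over-drilling)

    Preconditions: the three grids share one lattice, and drilling only
    removes material (``ideal ⊆ initial`` and ``actual ⊆ initial``).
    """
    if not (initial.same_lattice(ideal) and initial.same_lattice(actual)):
        raise ValidationError("initial, ideal and actual must share shape, spacing and origin")
    init = initial.mask
    for name, g in (("ideal", ideal), ("actual", actual)):
        excess = int(np.count_nonzero(g.mask & ~init))
        if excess:
            raise ValidationError(
                f"{name} mask contains {excess} voxel(s) outside the initial tooth mask"
            )
    a = actual.mask
    i = ideal.mask
    tp = int(np.count_nonzero(a & i))
    fp = int(np.count_nonzero(a & ~i))
    fn = int(np.count_nonzero(~a & i & init))
    tn = int(np.count_nonzero(~a & ~i & init))
    return ClassificationCounts(TP=tp, TN=tn, FP=fp, FN=fn)
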