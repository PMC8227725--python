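"""Core data model for SD-OCT volumes, retinal surfaces and pathology masks.

The coordinate convention throughout the package is: arrays are indexed
``(bscan, ascan, depth)`` with 0-based indices, depth increasing
posteriorly (toward the choroid), and half-open voxel intervals — a voxel
``k`` lies inside the slab ``[a, b)`` iff ``a <= k < b`` for float surface
depths ``a, b``.

The module also provides the two anatomical computations that everything
downstream depends on: Bruch's membrane as the per-B-scan convex hull of
the outer RPE boundary, and a deterministic rule-based segmenter that
recovers pathology labels (IRF/SRF/PED/SHRM) from rendered intensities by
thresholding within anatomically gated compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "LAYER_NAMES",
    "PATHOLOGY_CLASSES",
    "LABEL_CODES",
    "VoxelGeometry",
    "OCTVolume",
    "Surface",
    "LayerSet",
    "PathologyMask",
    "Contour",
    "compute_bruchs_membrane",
    "rule_based_segment",
    "masks_from_contours",
]

#: The 13 surfaces, anterior to posterior. The first twelve are retinal
#: boundaries (inner limiting membrane down to the outer RPE boundary);
#: Bruch's membrane (BM) is the derived thirteenth surface.
LAYER_NAMES: tuple[str, ...] = (
    "ILM",
    "RNFL-GCL",
    "GCL-IPL",
    "IPL-INL",
    "INL-OPL",
    "OPL-HFL",
    "ELM",
    "EZ",
    "OS",
    "IZ",
    "IB_RPE",
    "OB_RPE",
    "BM",
)

#: The four segmented pathology compartments.
PATHOLOGY_CLASSES: tuple[str, ...] = ("IRF", "SRF", "PED", "SHRM")

#: Integer codes used in label volumes. 0 is background ("none").
LABEL_CODES: dict[str, int] = {"none": 0, "IRF": 1, "SRF": 2, "PED": 3, "SHRM": 4}

#: Overlap resolution priority, most dominant first (posterior compartments win).
CLASS_PRIORITY: tuple[str, ...] = ("PED", "SHRM", "SRF", "IRF")


@dataclass(frozen=True)
class VoxelGeometry:
    """Scanner grid dimensions and physical voxel spacing.

    Parameters
    ----------
    n_bscans, n_ascans, n_depth
        Grid size along the slow lateral, fast lateral and axial axes.
    spacing_um
        ``(fast_lateral, slow_lateral, axial)`` voxel size in micrometres.
        The full-scale Cirrus preset is ``(11.7, 47.2, 2.0)``.
    """

    n_bscans: int
    n_ascans: int
    n_depth: int
    spacing_um: tuple[float, float, float] = (11.7, 47.2, 2.0)

    def __post_init__(self) -> None:
        if min(self.n_bscans, self.n_ascans, self.n_depth) < 1:
            raise ValueError(
                f"all grid dimensions must be >= 1, got "
                f"{self.n_bscans} x {self.n_ascans} x {self.n_depth}"
            )
        if min(self.spacing_um) <= 0:
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(n_bscans, n_ascans, n_depth)``."""
        return (self.n_bscans, self.n_ascans, self.n_depth)

    @property
    def voxel_volume_mm3(self) -> float:
        fast, slow, axial = self.spacing_um
        return fast * slow * axial * 1e-9

    @property
    def pixel_area_mm2(self) -> float:
        """En-face pixel area (fast x slow lateral spacing) in mm^2."""
        fast, slow, _ = self.spacing_um
        return fast * slow * 1e-6

    def enface_extent_mm(self) -> tuple[float, float]:
        fast, slow, _ = self.spacing_um
        return (self.n_ascans * fast * 1e-3, self.n_bscans * slow * 1e-3)


#: Full-scale Cirrus HD-OCT geometry: 6 x 6 x 2 mm field.
CIRRUS_FULL = VoxelGeometry(128, 512, 1024, (11.7, 47.2, 2.0))
#: Downscaled default for desk-scale experiments (same physical field).
CIRRUS_SMALL = VoxelGeometry(64, 128, 256, (46.8, 94.4, 8.0))
#: Aggressively downscaled preset for large simulated cohorts.
CIRRUS_TINY = VoxelGeometry(32, 64, 128, (93.6, 188.8, 16.0))

GEOMETRY_PRESETS: dict[str, VoxelGeometry] = {
    "full": CIRRUS_FULL,
    "small": CIRRUS_SMALL,
    "tiny": CIRRUS_TINY,
}


@dataclass
class OCTVolume:
    """A reflectivity volume on a :class:`VoxelGeometry` grid."""

    geometry: VoxelGeometry
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.intensities.shape != self.geometry.shape:
            raise ValueError(
                f"intensity array shape {self.intensities.shape} does not match "
                f"geometry {self.geometry.shape}"
            )


@dataclass
class Surface:
    """One retinal boundary: a depth value (in voxels) per en-face position."""

    name: str
    depth: np.ndarray  # (n_bscans, n_ascans) float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError(f"surface depth must be 2-D, got shape {self.depth.shape}")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError(f"surface {self.name!r} contains non-finite depths")


@dataclass
class LayerSet:
    """The ordered stack of 13 surfaces (ILM first, BM last)."""

    geometry: VoxelGeometry
    surfaces: list[Surface]

    def __post_init__(self) -> None:
        enface = (self.geometry.n_bscans, self.geometry.n_ascans)
        for s in self.surfaces:
            if s.depth.shape != enface:
                raise ValueError(
                    f"surface {s.name!r} shape {s.depth.shape} does not match "
                    f"en-face grid {enface}"
                )

    def __getitem__(self, name: str) -> Surface:
        for s in self.surfaces:
            if s.name == name:
                return s
        raise KeyError(f"no surface named {name!r}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.surfaces]

    def validate_ordering(self) -> None:
        """Raise if any adjacent pair violates anterior-to-posterior ordering."""
        for a, b in zip(self.surfaces, self.surfaces[1:]):
            if np.any(a.depth > b.depth + 1e-9):
                bad = np.argwhere(a.depth > b.depth + 1e-9)[0]
                raise ValueError(
                    f"ordering violated: {a.name} deeper than {b.name} at "
                    f"(bscan={bad[0]}, ascan={bad[1]})"
                )

    def stack(self) -> np.ndarray:
        return np.stack([s.depth for s in self.surfaces])


@dataclass
class PathologyMask:
    """Per-voxel pathology label volume (single label per voxel)."""

    geometry: VoxelGeometry
    labels: np.ndarray  # uint8 codes per LABEL_CODES

    def __post_init__(self) -> None:
        if self.labels.shape != self.geometry.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        self.labels = self.labels.astype(np.uint8, copy=False)

    def class_mask(self, cls: str) -> np.ndarray:
        if cls not in LABEL_CODES:
            raise ValueError(f"unknown pathology class {cls!r}")
        return self.labels == LABEL_CODES[cls]

    def class_voxels(self, cls: str) -> int:
        return int(np.count_nonzero(self.class_mask(cls)))

    def class_volume_mm3(self, cls: str) -> float:
        return self.class_voxels(cls) * self.geometry.voxel_volume_mm3

    def total_pathology_volume_mm3(self) -> float:
        return int(np.count_nonzero(self.labels)) * self.geometry.voxel_volume_mm3

    @classmethod
    def empty(cls, geometry: VoxelGeometry) -> "PathologyMask":
        return cls(geometry, np.zeros(geometry.shape, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Bruch's membrane


def _upper_envelope(x: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Posterior boundary of the 2-D convex hull of a depth profile.

    Works in an elevation frame (negated depth) so the posterior boundary is
    the lower convex chain, extracted from the counterclockwise Qhull vertex
    order and linearly interpolated back onto the sample grid.
    """
    pts = np.column_stack([x, -depth])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # All points collinear: the profile is its own hull.
        return depth.copy()
    verts = hull.vertices  # counterclockwise
    i_left = int(np.argmin(pts[verts, 0]))
    # Walk CCW from the leftmost vertex until the rightmost: the lower chain.
    order = np.roll(verts, -i_left)
    i_right = int(np.argmax(pts[order, 0]))
    chain = order[: i_right + 1]
    cx, cy = pts[chain, 0], pts[chain, 1]
    env = np.interp(x, cx, cy)
    return -env


def compute_bruchs_membrane(
    rpe_outer: Surface, geometry: VoxelGeometry
) -> Surface:
    """Construct Bruch's membrane as the convex hull of the outer RPE boundary.

    The hull is taken per B-scan in physical coordinates (lateral position in
    µm against depth in µm) and the posterior (maximal-depth) hull boundary is
    returned. Where the RPE is elevated — e.g. over a pigment epithelial
    detachment — the hull bridges the elevation, recovering the smooth
    membrane the RPE would rest on.

    Returns a surface with ``depth(BM) >= depth(RPE)`` pointwise, touching
    the RPE at hull vertices, and concave-down (second differences <= 0 in
    depth) along every B-scan.
    """
    if not np.all(np.isfinite(rpe_outer.depth)):
        raise ValueError("RPE surface contains non-finite depths")
    fast_um, _, axial_um = geometry.spacing_um
    x = np.arange(rpe_outer.depth.shape[1], dtype=float) * fast_um
    bm = np.empty_like(rpe_outer.depth)
    for b in range(rpe_outer.depth.shape[0]):
        profile_um = rpe_outer.depth[b] * axial_um
        bm[b] = _upper_envelope(x, profile_um) / axial_um
    # Guard against interpolation round-off dipping anterior to the RPE.
    np.maximum(bm, rpe_outer.depth, out=bm)
    return Surface("BM", bm)


# ---------------------------------------------------------------------------
# Rule-based segmentation

#: Rendered compartment intensities (arbitrary units in [0, 1]); see renderer.
INTENSITY = {
    "vitreous": 0.05,
    "inner_retina": 0.45,
    "outer_retina": 0.40,
    "subretinal_gap": 0.45,
    "rpe_band": 0.90,
    "choroid": 0.30,
    "IRF": 0.10,
    "SRF": 0.10,
    "PED": 0.12,
    "SHRM": 0.85,
}

DARK_THRESHOLD = 0.25
BRIGHT_THRESHOLD = 0.65


def _slab_mask(depth_idx: np.ndarray, top: np.ndarray, bottom: np.ndarray) -> np.ndarray:
    """Boolean volume for the half-open slab ``top <= k < bottom`` per column."""
    return (depth_idx >= top[..., None]) & (depth_idx < bottom[..., None])


def _filter_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1 or not mask.any():
        return mask
    # 26-connectivity: thin lesion fringes stay attached to their component.
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(lab, keep)


def rule_based_segment(
    volume: OCTVolume,
    layers: LayerSet,
    *,
    dark_threshold: float = DARK_THRESHOLD,
    bright_threshold: float = BRIGHT_THRESHOLD,
    min_component_voxels: int = 3,
) -> PathologyMask:
    """Segment IRF/SRF/PED/SHRM by thresholding within anatomical gates.

    Compartment gates come from the layer surfaces: intraretinal fluid is a
    dark region between ILM and ELM; subretinal fluid (dark) and subretinal
    hyperreflective material (bright) sit between the posterior retinal
    surface (IZ) and the inner RPE boundary; pigment epithelial detachment is
    the dark region between the outer RPE boundary and Bruch's membrane.
    Connected components smaller than ``min_component_voxels`` are discarded.
    Deterministic: no sampling, no fitted parameters.
    """
    if volume.geometry != layers.geometry:
        raise ValueError(
            f"volume geometry {volume.geometry.shape} does not match layer "
            f"geometry {layers.geometry.shape}"
        )
    geom = volume.geometry
    v = volume.intensities
    depth_idx = np.arange(geom.n_depth)[None, None, :]

    ilm = layers["ILM"].depth
    elm = layers["ELM"].depth
    iz = layers["IZ"].depth
    ib_rpe = layers["IB_RPE"].depth
    ob_rpe = layers["OB_RPE"].depth
    if "BM" in layers.names:
        bm = layers["BM"].depth
    else:
        bm = compute_bruchs_membrane(layers["OB_RPE"], geom).depth

    dark = v < dark_threshold
    bright = v > bright_threshold

    out = np.zeros(geom.shape, dtype=np.uint8)
    # Stamp in increasing priority so higher-priority classes overwrite.
    candidates = {
        "IRF": dark & _slab_mask(depth_idx, ilm, elm),
        "SRF": dark & _slab_mask(depth_idx, iz, ib_rpe),
        "SHRM": bright & _slab_mask(depth_idx, iz, ib_rpe),
        "PED": dark & _slab_mask(depth_idx, ob_rpe, bm),
    }
    for cls in reversed(CLASS_PRIORITY):
        m = _filter_small(candidates[cls], min_component_voxels)
        out[m] = LABEL_CODES[cls]
    return PathologyMask(geom, out)


# ---------------------------------------------------------------------------
# Contour rasterization


@dataclass(frozen=True)
class Contour:
    """A closed polygon annotation on one B-scan.

    ``points`` are ``(ascan, depth)`` vertex pairs; the polygon is closed,
    i.e. the first and last vertex must coincide.
    """

    bscan: int
    cls: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.cls not in PATHOLOGY_CLASSES:
            raise ValueError(f"unknown pathology class {self.cls!r}")
        if len(self.points) < 4 or self.points[0] != self.points[-1]:
            raise ValueError(
                f"contour on B-scan {self.bscan} is not closed: first and last "
                "vertices must coincide"
            )


def masks_from_contours(
    contours: Iterable[Contour],
    geometry: VoxelGeometry,
    priority: Sequence[str] = CLASS_PRIORITY,
) -> PathologyMask:
    """Rasterize per-B-scan contour annotations into a label volume.

    Overlapping contours of different classes are resolved by ``priority``
    (most dominant first; default PED > SHRM > SRF > IRF).
    """
    contours = list(contours)
    out = np.zeros(geometry.shape, dtype=np.uint8)
    for cls in reversed(list(priority)):
        for c in contours:
            if c.cls != cls:
                continue
            if not 0 <= c.bscan < geometry.n_bscans:
                raise ValueError(f"contour B-scan index {c.bscan} out of range")
            pts = np.asarray(c.points[:-1], dtype=float)
            rr, cc = _draw_polygon(
                pts[:, 1], pts[:, 0], shape=(geometry.n_depth, geometry.n_ascans)
            )
            out[c.bscan, cc, rr] = LABEL_CODES[cls]
    return PathologyMask(geometry, out)
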