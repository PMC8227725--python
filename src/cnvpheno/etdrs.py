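"""ETDRS-grid volumetric and thickness descriptors.

All descriptors are computed over central discs of radius 0.5, 1.5 and
3.0 mm around the fovea, in physical units: volumes in mm^3, heights and
thicknesses in µm, widths in mm. Per-B-scan quantities (height, width) are
combined across B-scans by taking the maximum; volumes are summed — the
C-scan reading of a B-scan-wise derivation.

The descriptor vocabulary is held in a :class:`FeatureRegistry`; the default
registry enumerates 105 descriptors: {volume, height, width} x 4 pathology
classes x 3 radii, plus {mean, min, max thickness, volume} x 6 layer pairs
x 3 radii, with the three ``subfield_volume`` entries of the
(IB_RPE, OPL-HFL) pair omitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .anatomy import (
    PATHOLOGY_CLASSES,
    LayerSet,
    PathologyMask,
    Surface,
    VoxelGeometry,
)

__all__ = [
    "DEFAULT_RADII_MM",
    "DiscSpec",
    "FeatureDef",
    "FeatureRegistry",
    "default_registry",
    "disc_mask",
    "cscan_volume",
    "cscan_height",
    "cscan_width",
    "subfield_thickness",
    "subfield_volume",
    "extract_features",
    "feature_table",
]

DEFAULT_RADII_MM: tuple[float, ...] = (0.5, 1.5, 3.0)

#: Layer pairs (posterior, anterior) whose slab thickness/volume is profiled.
DEFAULT_LAYER_PAIRS: tuple[tuple[str, str], ...] = (
    ("IB_RPE", "ILM"),
    ("BM", "ILM"),
    ("BM", "OB_RPE"),
    ("BM", "IB_RPE"),
    ("IB_RPE", "OPL-HFL"),
    ("OPL-HFL", "ILM"),
)


@dataclass(frozen=True)
class DiscSpec:
    """Centre (bscan, ascan — possibly fractional) and nested disc radii."""

    center: tuple[float, float]
    radii_mm: tuple[float, ...] = DEFAULT_RADII_MM

    def __post_init__(self) -> None:
        r = self.radii_mm
        if any(x <= 0 for x in r) or any(a >= b for a, b in zip(r, r[1:])):
            raise ValueError(f"radii must be positive and strictly increasing: {r}")

    @classmethod
    def foveal(cls, geometry: VoxelGeometry, radii_mm=DEFAULT_RADII_MM) -> "DiscSpec":
        """Disc centred on the en-face grid centre (the synthetic fovea)."""
        return cls(
            ((geometry.n_bscans - 1) / 2.0, (geometry.n_ascans - 1) / 2.0), radii_mm
        )


def disc_mask(
    geometry: VoxelGeometry, disc: DiscSpec, radius_mm: float
) -> np.ndarray:
    """Boolean en-face map of positions within ``radius_mm`` of the disc centre.

    A position is included iff the physical distance of its A-scan centre
    from the disc centre is <= the radius; masks nest across radii.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    fast_um, slow_um, _ = geometry.spacing_um
    cb, ca = disc.center
    bb, aa = np.meshgrid(
        np.arange(geometry.n_bscans), np.arange(geometry.n_ascans), indexing="ij"
    )
    d2 = ((aa - ca) * fast_um * 1e-3) ** 2 + ((bb - cb) * slow_um * 1e-3) ** 2
    return d2 <= radius_mm**2


def _check_class(cls: str) -> None:
    if cls not in PATHOLOGY_CLASSES:
        raise ValueError(f"unknown pathology class {cls!r}")


def cscan_volume(
    mask: PathologyMask, cls: str, disc: DiscSpec, radius_mm: float
) -> float:
    """Total volume (mm^3) of class voxels whose column lies inside the disc."""
    _check_class(cls)
    m = disc_mask(mask.geometry, disc, radius_mm)
    counts = (mask.labels == _code(cls)).sum(axis=2)
    return float(counts[m].sum()) * mask.geometry.voxel_volume_mm3


def cscan_height(
    mask: PathologyMask, cls: str, disc: DiscSpec, radius_mm: float
) -> float:
    """Maximal per-column labeled extent (µm) over in-disc A-scan columns."""
    _check_class(cls)
    m = disc_mask(mask.geometry, disc, radius_mm)
    counts = (mask.labels == _code(cls)).sum(axis=2)
    if not m.any():
        return 0.0
    axial_um = mask.geometry.spacing_um[2]
    return float(counts[m].max()) * axial_um


def cscan_width(
    mask: PathologyMask, cls: str, disc: DiscSpec, radius_mm: float
) -> float:
    """Maximal fast-axis footprint extent (mm), taken over B-scans.

    Per B-scan, the extent is ``(max_ascan - min_ascan + 1)`` of the class's
    in-disc footprint times the fast lateral spacing; the maximum across
    B-scans is returned, 0 if the class is absent.
    """
    _check_class(cls)
    geom = mask.geometry
    m = disc_mask(geom, disc, radius_mm)
    present = (mask.labels == _code(cls)).any(axis=2) & m  # (nb, na)
    if not present.any():
        return 0.0
    fast_um = geom.spacing_um[0]
    best = 0
    for b in np.flatnonzero(present.any(axis=1)):
        idx = np.flatnonzero(present[b])
        best = max(best, idx[-1] - idx[0] + 1)
    return best * fast_um * 1e-3


def _code(cls: str) -> int:
    from .anatomy import LABEL_CODES

    return LABEL_CODES[cls]


def _thickness_um(
    anterior: Surface, posterior: Surface, geometry: VoxelGeometry
) -> np.ndarray:
    diff = posterior.depth - anterior.depth
    if np.any(diff < -1e-9):
        bad = np.argwhere(diff < -1e-9)[0]
        raise ValueError(
            f"layer ordering violated: {anterior.name} posterior to "
            f"{posterior.name} at (bscan={bad[0]}, ascan={bad[1]})"
        )
    return np.clip(diff, 0.0, None) * geometry.spacing_um[2]


def subfield_thickness(
    anterior: Surface,
    posterior: Surface,
    geometry: VoxelGeometry,
    disc: DiscSpec,
    radius_mm: float,
    stat: str,
) -> float:
    """Slab thickness statistic (µm) over the in-disc en-face positions."""
    if stat not in ("mean", "min", "max"):
        raise ValueError(f"stat must be mean/min/max, got {stat!r}")
    th = _thickness_um(anterior, posterior, geometry)
    m = disc_mask(geometry, disc, radius_mm)
    vals = th[m]
    if vals.size == 0:
        return 0.0
    return float(getattr(np, stat)(vals))


def subfield_volume(
    anterior: Surface,
    posterior: Surface,
    geometry: VoxelGeometry,
    disc: DiscSpec,
    radius_mm: float,
) -> float:
    """Slab volume (mm^3): sum of in-disc thickness times en-face pixel area."""
    th = _thickness_um(anterior, posterior, geometry)
    m = disc_mask(geometry, disc, radius_mm)
    return float(th[m].sum()) * 1e-3 * geometry.pixel_area_mm2


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class FeatureDef:
    """One named descriptor: its kind, target and disc radius."""

    kind: str  # cscan_volume | cscan_height | cscan_width |
    #            subfield_thickness_{mean,min,max} | subfield_volume
    target: str | tuple[str, str]  # pathology class or (posterior, anterior) pair
    radius_mm: float

    @property
    def name(self) -> str:
        if self.kind.startswith("cscan"):
            return f"{self.kind}_{self.target}_{self.radius_mm:g}mm"
        post, ant = self.target
        base = f"{post}-to-{ant}_{self.radius_mm:g}mm"
        if self.kind == "subfield_volume":
            return f"subfield_volume_{base}"
        stat = self.kind.rsplit("_", 1)[1]
        return f"subfield_thickness_{base}_{stat}"

    @property
    def units(self) -> str:
        return {
            "cscan_volume": "mm3",
            "cscan_height": "um",
            "cscan_width": "mm",
            "subfield_volume": "mm3",
        }.get(self.kind, "um")


_NAME_RE = re.compile(
    r"^(?P<kind>cscan_(?:volume|height|width)|subfield_volume|"
    r"subfield_thickness)_(?P<target>.+?)_(?P<radius>[\d.]+)mm(?:_(?P<stat>mean|min|max))?$"
)


def parse_feature_name(name: str) -> FeatureDef:
    """Invert :attr:`FeatureDef.name`."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable feature name {name!r}")
    kind, target, radius = m["kind"], m["target"], float(m["radius"])
    if kind == "subfield_thickness":
        if m["stat"] is None:
            raise ValueError(f"thickness feature {name!r} lacks a statistic suffix")
        kind = f"subfield_thickness_{m['stat']}"
    if kind.startswith("cscan"):
        return FeatureDef(kind, target, radius)
    post, ant = target.split("-to-")
    return FeatureDef(kind, (post, ant), radius)


@dataclass
class FeatureRegistry:
    """Ordered, uniquely named collection of descriptor definitions."""

    entries: list[FeatureDef]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def default_registry(
    radii_mm: tuple[float, ...] = DEFAULT_RADII_MM,
    layer_pairs: tuple[tuple[str, str], ...] = DEFAULT_LAYER_PAIRS,
) -> FeatureRegistry:
    """The default 105-descriptor registry (see module docstring)."""
    entries: list[FeatureDef] = []
    for cls in PATHOLOGY_CLASSES:
        for r in radii_mm:
            for kind in ("cscan_volume", "cscan_height", "cscan_width"):
                entries.append(FeatureDef(kind, cls, r))
    for pair in layer_pairs:
        for r in radii_mm:
            for stat in ("mean", "min", "max"):
                entries.append(FeatureDef(f"subfield_thickness_{stat}", pair, r))
            # The (IB_RPE, OPL-HFL) slab is profiled by thickness only.
            if pair != ("IB_RPE", "OPL-HFL"):
                entries.append(FeatureDef("subfield_volume", pair, r))
    return FeatureRegistry(entries)


def extract_features(
    mask: PathologyMask,
    layers: LayerSet,
    registry: FeatureRegistry,
    disc: DiscSpec | None = None,
) -> pd.Series:
    """Compute one value per registry entry for a single eye.

    Returns a Series indexed by feature name, in registry order. Any entry
    whose preconditions fail aborts the whole eye with the entry named.
    """
    if mask.geometry != layers.geometry:
        raise ValueError("mask and layer geometries differ")
    geom = mask.geometry
    if disc is None:
        disc = DiscSpec.foveal(geom)
    values: dict[str, float] = {}
    for e in registry:
        try:
            if e.kind == "cscan_volume":
                v = cscan_volume(mask, e.target, disc, e.radius_mm)
            elif e.kind == "cscan_height":
                v = cscan_height(mask, e.target, disc, e.radius_mm)
            elif e.kind == "cscan_width":
                v = cscan_width(mask, e.target, disc, e.radius_mm)
            else:
                post, ant = e.target
                a, p = layers[ant], layers[post]
                if e.kind == "subfield_volume":
                    v = subfield_volume(a, p, geom, disc, e.radius_mm)
                else:
                    stat = e.kind.rsplit("_", 1)[1]
                    v = subfield_thickness(a, p, geom, disc, e.radius_mm, stat)
        except Exception as err:
            raise RuntimeError(f"feature {e.name!r} failed: {err}") from err
        values[e.name] = v
    return pd.Series(values, dtype=float)


def feature_table(
    eyes: Iterable,
    registry: FeatureRegistry | None = None,
    *,
    segmenter=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (eyes x descriptors) and label vector for a cohort.

    ``eyes`` yields objects with ``eye_id``, ``label``, ``layers`` and either
    a ``truth_mask`` (used directly when ``segmenter`` is None) or a
    ``volume`` passed through ``segmenter(volume, layers)``.
    """
    if registry is None:
        registry = default_registry()
    rows, labels, ids = [], [], []
    for eye in eyes:
        mask = eye.truth_mask if segmenter is None else segmenter(eye.volume, eye.layers)
        rows.append(extract_features(mask, eye.layers, registry))
        labels.append(eye.label)
        ids.append(eye.eye_id)
    X = pd.DataFrame(rows, index=pd.Index(ids, name="eye_id"))
    y = pd.Series(labels, index=X.index, name="label")
    return X, y
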