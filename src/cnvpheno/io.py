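"""File-format plumbing: TIFF volumes, tabular surfaces, manifests, configs.

Volumes and label masks are written as multi-page TIFF (one page per
B-scan) with a JSON sidecar naming the label integers and recording the
voxel geometry. Layer surfaces travel as long-format CSV
(eye_id, surface_name, bscan_index, ascan_index, depth_voxels); cohort
manifests as CSV; cohort/experiment configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .anatomy import (
    LABEL_CODES,
    LAYER_NAMES,
    LayerSet,
    OCTVolume,
    PathologyMask,
    Surface,
    VoxelGeometry,
)
from .synthetic import DEFAULT_EFFECTS, CohortSpec, EffectParams, SyntheticEye

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_layers",
    "read_layers",
    "write_cohort",
    "cohort_spec_from_yaml",
    "cohort_spec_to_yaml",
]


def _geometry_sidecar(geometry: VoxelGeometry, extra: dict | None = None) -> dict:
    d = {
        "n_bscans": geometry.n_bscans,
        "n_ascans": geometry.n_ascans,
        "n_depth": geometry.n_depth,
        "spacing_um": list(geometry.spacing_um),
    }
    if extra:
        d.update(extra)
    return d


def _geometry_from_sidecar(d: dict) -> VoxelGeometry:
    return VoxelGeometry(
        d["n_bscans"], d["n_ascans"], d["n_depth"], tuple(d["spacing_um"])
    )


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    path = Path(path)
    # One TIFF page per B-scan: (depth, ascan) so pages read as B-scan images.
    pages = np.transpose(volume.intensities, (0, 2, 1)).astype(np.float32)
    tifffile.imwrite(path, pages)
    path.with_suffix(".json").write_text(
        json.dumps(_geometry_sidecar(volume.geometry), indent=1)
    )


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = _geometry_from_sidecar(meta)
    return OCTVolume(geom, np.transpose(pages, (0, 2, 1)).astype(np.float32))


def write_mask(mask: PathologyMask, path: str | Path) -> None:
    path = Path(path)
    pages = np.transpose(mask.labels, (0, 2, 1))
    tifffile.imwrite(path, pages)
    path.with_suffix(".json").write_text(
        json.dumps(
            _geometry_sidecar(mask.geometry, {"label_codes": LABEL_CODES}), indent=1
        )
    )


def read_mask(path: str | Path) -> PathologyMask:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = _geometry_from_sidecar(meta)
    return PathologyMask(geom, np.transpose(pages, (0, 2, 1)).astype(np.uint8))


def write_layers(eye_id: str, layers: LayerSet, path: str | Path) -> None:
    nb, na = layers.geometry.n_bscans, layers.geometry.n_ascans
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    frames = []
    for s in layers.surfaces:
        frames.append(
            pd.DataFrame(
                {
                    "eye_id": eye_id,
                    "surface_name": s.name,
                    "bscan_index": bb.ravel(),
                    "ascan_index": aa.ravel(),
                    "depth_voxels": s.depth.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_layers(path: str | Path, geometry: VoxelGeometry) -> LayerSet:
    df = pd.read_csv(path)
    surfaces = []
    for name in LAYER_NAMES:
        sub = df[df["surface_name"] == name]
        if sub.empty:
            raise ValueError(f"surface {name!r} missing from {path}")
        depth = np.zeros((geometry.n_bscans, geometry.n_ascans))
        depth[sub["bscan_index"], sub["ascan_index"]] = sub["depth_voxels"]
        surfaces.append(Surface(name, depth))
    return LayerSet(geometry, surfaces)


def write_cohort(eyes, out_dir: str | Path) -> Path:
    """Write volumes, masks and surfaces for a cohort; return the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in eyes:
        vol_path = out / f"{eye.eye_id}_volume.tif"
        mask_path = out / f"{eye.eye_id}_mask.tif"
        layer_path = out / f"{eye.eye_id}_layers.csv"
        write_volume(eye.volume, vol_path)
        write_mask(eye.truth_mask, mask_path)
        write_layers(eye.eye_id, eye.layers, layer_path)
        rows.append(
            {
                "eye_id": eye.eye_id,
                "label": eye.label,
                "volume": vol_path.name,
                "mask": mask_path.name,
                "layers": layer_path.name,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    d = {
        "n_per_class": dict(spec.n_per_class),
        "geometry": _geometry_sidecar(spec.geometry),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "effect_params": {
            cls: {
                "irf": list(p.irf),
                "srf": list(p.srf),
                "ped": list(p.ped),
                "shrm": list(p.shrm),
            }
            for cls, p in spec.effect_params.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    effects = {
        cls: EffectParams(
            irf=tuple(p["irf"]),
            srf=tuple(p["srf"]),
            ped=tuple(p["ped"]),
            shrm=tuple(p["shrm"]),
        )
        for cls, p in d.get("effect_params", {}).items()
    } or dict(DEFAULT_EFFECTS)
    return CohortSpec(
        n_per_class=d["n_per_class"],
        geometry=_geometry_from_sidecar(d["geometry"]),
        effect_params=effects,
        noise_sd=d.get("noise_sd", 0.05),
        seed=d.get("seed", 0),
    )
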