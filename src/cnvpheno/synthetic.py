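"""Synthetic SD-OCT cohort generator.

Emulates the statistical structure the downstream analysis assumes: smooth
ordered retinal surfaces with a foveal pit, class-conditional lesion burden
(predominantly classic CNV carries high SHRM and low PED volume, occult the
reverse, minimally classic a mixture, controls near-zero pathology), and a
simple piecewise-constant reflectivity rendering so the rule-based segmenter
has realistic input. Everything is reproducible from a single seed.

Lesions are half-ellipsoid domes (SRF/SHRM/PED, which deform the overlying
surfaces) or full ellipsoids (IRF cysts) with jittered centres, radii and
aspect ratios; class-conditional total volumes are drawn from log-normal
distributions so burdens are non-negative and right-skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .anatomy import (
    LABEL_CODES,
    LAYER_NAMES,
    PATHOLOGY_CLASSES,
    CIRRUS_SMALL,
    INTENSITY,
    LayerSet,
    OCTVolume,
    PathologyMask,
    Surface,
    VoxelGeometry,
)

__all__ = [
    "FA_CLASSES",
    "EffectParams",
    "CohortSpec",
    "SyntheticEye",
    "generate_layers",
    "generate_pathology",
    "render_volume",
    "generate_cohort",
    "iter_cohort",
    "DEFAULT_EFFECTS",
]

#: Fluorescein-angiography phenotype labels.
FA_CLASSES: tuple[str, ...] = (
    "none",
    "occult",
    "minimally_classic",
    "predominantly_classic",
)

#: Eyes labelled "none" must stay below this total pathology volume (mm^3).
NO_CNV_VOLUME_CAP_MM3 = 1e-3


@dataclass(frozen=True)
class EffectParams:
    """Per-class lesion-burden distributions: (mean, sd) of total volume in mm^3.

    Volumes are drawn from a log-normal parameterized by these moments.
    A mean of 0 means the compartment is absent for that class.
    """

    irf: tuple[float, float]
    srf: tuple[float, float]
    ped: tuple[float, float]
    shrm: tuple[float, float]

    def mean(self, cls: str) -> float:
        return getattr(self, cls.lower())[0]


#: Default class-conditional lesion burdens. Predominantly classic: high SHRM,
#: low PED; occult: the reverse; minimally classic: intermediate in both.
DEFAULT_EFFECTS: dict[str, EffectParams] = {
    "none": EffectParams((0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
    "occult": EffectParams(
        irf=(0.08, 0.06), srf=(0.15, 0.10), ped=(0.60, 0.35), shrm=(0.05, 0.04)
    ),
    "minimally_classic": EffectParams(
        irf=(0.10, 0.07), srf=(0.20, 0.12), ped=(0.35, 0.22), shrm=(0.20, 0.14)
    ),
    "predominantly_classic": EffectParams(
        irf=(0.10, 0.07), srf=(0.20, 0.12), ped=(0.10, 0.08), shrm=(0.55, 0.30)
    ),
}


def _validate_effects(effects: dict[str, EffectParams]) -> None:
    pc, oc = effects["predominantly_classic"], effects["occult"]
    mc = effects.get("minimally_classic")
    if not pc.mean("SHRM") > pc.mean("PED"):
        raise ValueError("predominantly_classic must have mean SHRM > mean PED")
    if not oc.mean("PED") > oc.mean("SHRM"):
        raise ValueError("occult must have mean PED > mean SHRM")
    if mc is not None:
        lo_s, hi_s = sorted((oc.mean("SHRM"), pc.mean("SHRM")))
        lo_p, hi_p = sorted((oc.mean("PED"), pc.mean("PED")))
        if not (lo_s <= mc.mean("SHRM") <= hi_s and lo_p <= mc.mean("PED") <= hi_p):
            raise ValueError(
                "minimally_classic lesion burdens must lie between the occult "
                "and predominantly_classic means"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible synthetic cohort."""

    n_per_class: dict[str, int]
    geometry: VoxelGeometry = CIRRUS_SMALL
    effect_params: dict[str, EffectParams] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in FA_CLASSES:
                raise ValueError(f"unknown FA class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")
        _validate_effects(self.effect_params)

    @property
    def n_total(self) -> int:
        return sum(self.n_per_class.values())


@dataclass
class SyntheticEye:
    """One simulated eye: volume, ground-truth mask, surfaces and FA label."""

    eye_id: str
    label: str
    volume: OCTVolume
    truth_mask: PathologyMask
    layers: LayerSet


# ---------------------------------------------------------------------------
# Surfaces


def _smooth_field(rng: np.ndarray, shape: tuple[int, int], sigma: float, amp: float):
    f = rng.normal(size=shape)
    f = ndimage.gaussian_filter(f, sigma=sigma, mode="nearest")
    sd = f.std()
    return f * (amp / sd) if sd > 0 else f


def generate_layers(geometry: VoxelGeometry, seed: int) -> LayerSet:
    """Generate 13 smooth, strictly ordered surfaces with a foveal pit.

    The twelve retinal boundaries share a low-frequency undulation field
    (layers run parallel); the foveal depression thins the inner retina at
    the en-face grid centre and fades toward the outer boundaries. Bruch's
    membrane is the smooth posterior baseline of the (undeformed) RPE.
    """
    rng = np.random.default_rng(seed)
    nb, na, nd = geometry.shape
    _, _, axial_um = geometry.spacing_um
    enface = (nb, na)

    # Posterior baseline of the retina (pre-pathology outer RPE == BM).
    base = 0.55 * nd + _smooth_field(rng, enface, sigma=max(nb, na) / 8, amp=0.01 * nd)

    retina_um = rng.uniform(290.0, 330.0)  # ILM -> inner RPE, healthy macula
    rpe_um = rng.uniform(18.0, 26.0)
    gap_um = 6.0  # photoreceptor tips to RPE contact zone
    retina_vox = retina_um / axial_um
    rpe_vox = max(rpe_um / axial_um, 1.0)
    gap_vox = gap_um / axial_um

    # Fractional depth of each boundary through the neurosensory retina.
    fractions = {
        "ILM": 0.0,
        "RNFL-GCL": 0.08,
        "GCL-IPL": 0.16,
        "IPL-INL": 0.24,
        "INL-OPL": 0.32,
        "OPL-HFL": 0.42,
        "ELM": 0.72,
        "EZ": 0.80,
        "OS": 0.88,
        "IZ": 1.0,
    }

    # Foveal pit: inner surfaces dip posteriorly at the centre, attenuated
    # with fractional depth so outer boundaries are untouched.
    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    fast_um, slow_um, _ = geometry.spacing_um
    cx, cy = (nb - 1) / 2.0, (na - 1) / 2.0
    r2_mm2 = ((aa - cy) * fast_um * 1e-3) ** 2 + ((bb - cx) * slow_um * 1e-3) ** 2
    pit_um = rng.uniform(90.0, 130.0)
    pit = (pit_um / axial_um) * np.exp(-r2_mm2 / (2 * 0.35**2))

    ib_rpe = base - rpe_vox
    iz = ib_rpe - gap_vox
    ilm = iz - retina_vox

    surfaces: list[Surface] = []
    for name in LAYER_NAMES[:10]:
        f = fractions[name]
        depth = ilm + f * retina_vox + (1.0 - f) * pit
        surfaces.append(Surface(name, depth))
    surfaces.append(Surface("IB_RPE", ib_rpe))
    surfaces.append(Surface("OB_RPE", base.copy()))
    surfaces.append(Surface("BM", base.copy()))

    # Clamp into the axial range and enforce ordering numerically.
    stack = np.stack([s.depth for s in surfaces])
    np.clip(stack, 1.0, nd - 2.0, out=stack)
    np.maximum.accumulate(stack, axis=0, out=stack)
    layers = LayerSet(geometry, [Surface(n, d) for n, d in zip(LAYER_NAMES, stack)])
    layers.validate_ordering()
    return layers


# ---------------------------------------------------------------------------
# Pathology


def _lognormal(rng, mean: float, sd: float) -> float:
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _dome_elevation_vox(
    geometry: VoxelGeometry, rng, center_mm: tuple[float, float], volume_mm3: float
) -> np.ndarray:
    """En-face elevation map (in voxels) of a half-ellipsoid dome of given volume."""
    nb, na, _ = geometry.shape
    fast_um, slow_um, axial_um = geometry.spacing_um
    kappa = rng.uniform(0.2, 0.6)  # height / lateral radius
    r_mm = (3.0 * volume_mm3 / (2.0 * np.pi * kappa)) ** (1.0 / 3.0)
    h_mm = kappa * r_mm
    ecc = rng.uniform(0.7, 1.4)  # lateral anisotropy
    ra, rb = r_mm * ecc, r_mm / ecc

    bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    x_mm = aa * fast_um * 1e-3
    y_mm = bb * slow_um * 1e-3
    u = ((x_mm - center_mm[0]) / ra) ** 2 + ((y_mm - center_mm[1]) / rb) ** 2
    h_vox = h_mm * 1e3 / axial_um
    return h_vox * np.sqrt(np.clip(1.0 - u, 0.0, None))


def _jittered_center_mm(geometry: VoxelGeometry, rng, spread_mm: float = 1.2):
    w_mm, h_mm = geometry.enface_extent_mm()
    cx, cy = w_mm / 2.0, h_mm / 2.0
    return (
        cx + rng.uniform(-spread_mm, spread_mm),
        cy + rng.uniform(-spread_mm, spread_mm),
    )


def _split_volume(rng, total: float) -> list[float]:
    n = int(rng.integers(1, 4))
    w = rng.dirichlet(np.ones(n) * 2.0)
    return [total * float(wi) for wi in w]


def generate_pathology(
    layers: LayerSet,
    label: str,
    effect_params: dict[str, EffectParams],
    seed: int,
) -> tuple[PathologyMask, LayerSet]:
    """Plant class-conditional lesions and return the mask plus adjusted surfaces.

    PED domes elevate the whole retina+RPE complex above Bruch's membrane and
    fill the created space; SRF and SHRM domes lift the neurosensory retina
    off the RPE; IRF cysts are ellipsoids inside the inner retina and leave
    surfaces unchanged. Voxels are stamped single-label in priority order
    PED > SHRM > SRF > IRF. The input LayerSet is not modified.
    """
    if label not in FA_CLASSES:
        raise ValueError(f"unknown FA class {label!r}")
    geom = layers.geometry
    rng = np.random.default_rng(seed)
    params = effect_params[label]
    stack = layers.stack().copy()  # (13, nb, na)
    nd = geom.n_depth
    labels = np.zeros(geom.shape, dtype=np.uint8)
    depth_idx = np.arange(nd)[None, None, :]

    targets = {
        cls: _lognormal(rng, *getattr(params, cls.lower()))
        for cls in PATHOLOGY_CLASSES
    }

    regions: dict[str, np.ndarray] = {}

    # --- PED: elevate surfaces 0..11 (ILM..OB_RPE) above the fixed BM.
    if targets["PED"] > 0:
        elev = np.zeros(stack[0].shape)
        for v in _split_volume(rng, targets["PED"]):
            elev += _dome_elevation_vox(geom, rng, _jittered_center_mm(geom, rng), v)
        elev = np.minimum(elev, stack[0] - 2.0)  # keep the ILM in range
        stack[:12] -= elev[None]
        regions["PED"] = (depth_idx >= stack[11][..., None]) & (
            depth_idx < stack[12][..., None]
        )

    # --- SRF and SHRM: lift surfaces 0..9 (retina) off the inner RPE.
    for cls in ("SRF", "SHRM"):
        if targets[cls] <= 0:
            continue
        elev = np.zeros(stack[0].shape)
        for v in _split_volume(rng, targets[cls]):
            elev += _dome_elevation_vox(geom, rng, _jittered_center_mm(geom, rng), v)
        elev = np.minimum(elev, stack[0] - 2.0)
        lower = stack[9].copy()  # IZ before this lift
        stack[:10] -= elev[None]
        regions[cls] = (depth_idx >= stack[9][..., None]) & (
            depth_idx < lower[..., None]
        )

    # --- IRF: ellipsoidal cysts inside the inner retina (ILM..ELM).
    if targets["IRF"] > 0:
        fast_um, slow_um, axial_um = geom.spacing_um
        nb, na, _ = geom.shape
        bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        x_mm = aa * fast_um * 1e-3
        y_mm = bb * slow_um * 1e-3
        irf = np.zeros(geom.shape, dtype=bool)
        for v in _split_volume(rng, targets["IRF"]):
            kappa = rng.uniform(0.15, 0.4)
            r_mm = (3.0 * v / (4.0 * np.pi * kappa)) ** (1.0 / 3.0)
            c_mm = kappa * r_mm
            cx_mm, cy_mm = _jittered_center_mm(geom, rng)
            u = ((x_mm - cx_mm) / r_mm) ** 2 + ((y_mm - cy_mm) / r_mm) ** 2
            half = (c_mm * 1e3 / axial_um) * np.sqrt(np.clip(1.0 - u, 0.0, None))
            mid = 0.5 * (stack[0] + stack[6])  # between ILM and ELM
            top = mid - half
            bot = mid + half
            inside = (depth_idx >= top[..., None]) & (depth_idx < bot[..., None])
            # Clip to the inner-retina compartment.
            inside &= (depth_idx >= stack[0][..., None]) & (
                depth_idx < stack[6][..., None]
            )
            irf |= inside
        regions["IRF"] = irf

    for cls in ("IRF", "SRF", "SHRM", "PED"):  # increasing priority
        if cls in regions:
            labels[regions[cls]] = LABEL_CODES[cls]

    # Drop sub-resolution fragments (< 3 voxels) left where a higher-priority
    # lesion carved through a blob: rasterization artifacts, not lesions.
    from .anatomy import _filter_small

    for cls in PATHOLOGY_CLASSES:
        m = labels == LABEL_CODES[cls]
        labels[m & ~_filter_small(m, 3)] = 0

    new_layers = LayerSet(
        geom, [Surface(n, d) for n, d in zip(LAYER_NAMES, stack)]
    )
    new_layers.validate_ordering()
    return PathologyMask(geom, labels), new_layers


# ---------------------------------------------------------------------------
# Rendering


def render_volume(
    layers: LayerSet, mask: PathologyMask, noise_sd: float, seed: int
) -> OCTVolume:
    """Render a reflectivity volume from surfaces and a pathology mask.

    Compartments get characteristic constant intensities (fluids dark, SHRM
    and the RPE band bright) plus additive Gaussian noise, clipped to [0, 1].
    With ``noise_sd=0`` the output is exactly piecewise constant.
    """
    geom = layers.geometry
    if mask.geometry != geom:
        raise ValueError("mask geometry does not match layer geometry")
    depth_idx = np.arange(geom.n_depth)[None, None, :]
    s = {name: layers[name].depth[..., None] for name in layers.names}

    v = np.full(geom.shape, INTENSITY["vitreous"], dtype=np.float32)
    v[(depth_idx >= s["ILM"]) & (depth_idx < s["OPL-HFL"])] = INTENSITY["inner_retina"]
    v[(depth_idx >= s["OPL-HFL"]) & (depth_idx < s["IZ"])] = INTENSITY["outer_retina"]
    v[(depth_idx >= s["IZ"]) & (depth_idx < s["IB_RPE"])] = INTENSITY["subretinal_gap"]
    v[(depth_idx >= s["IB_RPE"]) & (depth_idx < s["OB_RPE"])] = INTENSITY["rpe_band"]
    v[depth_idx >= s["OB_RPE"]] = INTENSITY["choroid"]

    for cls in PATHOLOGY_CLASSES:
        v[mask.class_mask(cls)] = INTENSITY[cls]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=geom.shape).astype(np.float32)
        np.clip(v, 0.0, 1.0, out=v)
    return OCTVolume(geom, v)


# ---------------------------------------------------------------------------
# Cohort assembly


def _make_eye(spec: CohortSpec, label: str, index: int, seed_seq) -> SyntheticEye:
    s_layers, s_path, s_noise = seed_seq.spawn(3)
    layers = generate_layers(spec.geometry, int(s_layers.generate_state(1)[0] % 2**31))
    mask, layers = generate_pathology(
        layers, label, spec.effect_params, int(s_path.generate_state(1)[0] % 2**31)
    )
    vol = render_volume(
        layers, mask, spec.noise_sd, int(s_noise.generate_state(1)[0] % 2**31)
    )
    return SyntheticEye(f"{label}_{index:04d}", label, vol, mask, layers)


def iter_cohort(spec: CohortSpec):
    """Yield :class:`SyntheticEye` objects one at a time (memory-flat).

    Seeding is keyed per (class, index) so the cohort is reproducible and
    individual eyes can be regenerated without building the whole cohort.
    """
    for cls in FA_CLASSES:
        n = spec.n_per_class.get(cls, 0)
        for i in range(n):
            child = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(FA_CLASSES.index(cls), i)
            )
            yield _make_eye(spec, cls, i, child)


def generate_cohort(spec: CohortSpec) -> list[SyntheticEye]:
    """Materialize the full cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(spec))
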