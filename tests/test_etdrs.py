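"""ETDRS-grid descriptors: worked examples, nesting, units, registry."""

import numpy as np
import pandas as pd
import pytest

import cnvpheno as c
from cnvpheno.anatomy import LABEL_CODES
from cnvpheno.etdrs import (
    DEFAULT_RADII_MM,
    DiscSpec,
    default_registry,
    parse_feature_name,
)

FULL = c.CIRRUS_FULL  # 128 x 512 x 1024 @ (11.7, 47.2, 2.0) um


def _mask_with_voxels(geom, voxels, cls="PED"):
    labels = np.zeros(geom.shape, dtype=np.uint8)
    for b, a, d in voxels:
        labels[b, a, d] = LABEL_CODES[cls]
    return c.PathologyMask(geom, labels)


def _flat_layers(geom, depths):
    surfaces = [
        c.Surface(n, np.full((geom.n_bscans, geom.n_ascans), float(d)))
        for n, d in zip(c.LAYER_NAMES, depths)
    ]
    return c.LayerSet(geom, surfaces)


class TestDiscMask:
    def test_nesting(self):
        disc = DiscSpec.foveal(FULL)
        areas = [c.disc_mask(FULL, disc, r).sum() for r in DEFAULT_RADII_MM]
        masks = [c.disc_mask(FULL, disc, r) for r in DEFAULT_RADII_MM]
        assert areas[0] < areas[1] < areas[2]
        assert np.all(masks[0] <= masks[1]) and np.all(masks[1] <= masks[2])

    def test_tiny_radius_only_center(self):
        geom = c.VoxelGeometry(9, 9, 8, (100.0, 100.0, 10.0))
        disc = DiscSpec((4, 4), (0.04, 1.5, 3.0))
        m = c.disc_mask(geom, disc, 0.04)  # below half of the lateral spacing
        assert m.sum() == 1 and m[4, 4]

    def test_full_scale_3mm_disc_area(self):
        """Pixel-counted disc area matches pi*r^2 within 2% at full resolution."""
        disc = DiscSpec.foveal(FULL)
        area = c.disc_mask(FULL, disc, 3.0).sum() * FULL.pixel_area_mm2
        assert area == pytest.approx(np.pi * 9.0, rel=0.02)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            c.disc_mask(FULL, DiscSpec.foveal(FULL), -1.0)

    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            DiscSpec((0, 0), (1.5, 0.5, 3.0))


class TestCscanDescriptors:
    def test_empty_mask_all_zero(self):
        geom = c.CIRRUS_TINY
        mask = c.PathologyMask.empty(geom)
        disc = DiscSpec.foveal(geom)
        assert c.cscan_volume(mask, "PED", disc, 3.0) == 0.0
        assert c.cscan_height(mask, "PED", disc, 3.0) == 0.0
        assert c.cscan_width(mask, "PED", disc, 3.0) == 0.0

    def test_single_voxel_volume_is_voxel_volume(self):
        # One voxel at the disc centre: 11.7 x 47.2 x 2.0 um^3 = 1.10448e-6 mm^3
        disc = DiscSpec.foveal(FULL)
        mask = _mask_with_voxels(FULL, [(64, 256, 500)])
        v = c.cscan_volume(mask, "PED", disc, 0.5)
        assert v == pytest.approx(1.10448e-6, rel=1e-9)

    def test_volume_nesting_for_off_center_voxel(self):
        # A voxel ~1.0 mm from the centre along the fast axis.
        disc = DiscSpec.foveal(FULL)
        a = int(round(255.5 + 1000.0 / 11.7))
        mask = _mask_with_voxels(FULL, [(64, a, 500)])
        assert c.cscan_volume(mask, "PED", disc, 0.5) == 0.0
        v15 = c.cscan_volume(mask, "PED", disc, 1.5)
        v30 = c.cscan_volume(mask, "PED", disc, 3.0)
        assert v15 == v30 > 0

    def test_height_counts_column_voxels(self):
        disc = DiscSpec.foveal(FULL)
        vox = [(64, 256, 500 + k) for k in range(10)]
        mask = _mask_with_voxels(FULL, vox)
        assert c.cscan_height(mask, "PED", disc, 3.0) == pytest.approx(20.0)

    def test_height_is_max_over_columns(self):
        disc = DiscSpec.foveal(FULL)
        vox = [(64, 250, 500 + k) for k in range(5)]
        vox += [(64, 260, 500 + k) for k in range(8)]
        mask = _mask_with_voxels(FULL, vox)
        assert c.cscan_height(mask, "PED", disc, 3.0) == pytest.approx(16.0)

    def test_width_extent_rule(self):
        disc = DiscSpec.foveal(FULL)
        vox = [(64, a, 500) for a in range(250, 260)]  # A-scans 250..259
        mask = _mask_with_voxels(FULL, vox, cls="SHRM")
        assert c.cscan_width(mask, "SHRM", disc, 3.0) == pytest.approx(0.117)

    def test_width_single_column(self):
        disc = DiscSpec.foveal(FULL)
        mask = _mask_with_voxels(FULL, [(64, 256, 500)], cls="SHRM")
        assert c.cscan_width(mask, "SHRM", disc, 3.0) == pytest.approx(0.0117)

    def test_unknown_class_rejected(self):
        geom = c.CIRRUS_TINY
        with pytest.raises(ValueError, match="class"):
            c.cscan_volume(
                c.PathologyMask.empty(geom), "CNV", DiscSpec.foveal(geom), 1.5
            )


class TestSubfieldDescriptors:
    def test_flat_slab_thickness(self):
        depths = list(np.linspace(100, 280, 12)) + [300]
        layers = _flat_layers(FULL, depths)
        disc = DiscSpec.foveal(FULL)
        ilm, bm = layers["ILM"], layers["BM"]
        for stat in ("mean", "min", "max"):
            t = c.subfield_thickness(ilm, bm, FULL, disc, 1.5, stat)
            assert t == pytest.approx((300 - 100) * 2.0)

    def test_min_le_mean_le_max(self, fixture_cohort):
        eye = next(e for e in fixture_cohort if e.label == "occult")
        geom = eye.volume.geometry
        disc = DiscSpec.foveal(geom)
        a, b = eye.layers["ILM"], eye.layers["BM"]
        vals = {
            s: c.subfield_thickness(a, b, geom, disc, 3.0, s)
            for s in ("min", "mean", "max")
        }
        assert vals["min"] <= vals["mean"] <= vals["max"]

    def test_identical_layers_zero(self):
        layers = _flat_layers(FULL, [200] * 13)
        disc = DiscSpec.foveal(FULL)
        s = layers["ILM"]
        for stat in ("mean", "min", "max"):
            assert c.subfield_thickness(s, s, FULL, disc, 0.5, stat) == 0.0
        assert c.subfield_volume(s, s, FULL, disc, 0.5) == 0.0

    def test_ordering_violation_reported(self):
        layers = _flat_layers(FULL, [200] * 13)
        shallow, deep = layers["ILM"], layers["BM"]
        deep.depth[3, 7] = 150.0  # BM anterior to ILM at one position
        with pytest.raises(ValueError, match="bscan=3, ascan=7"):
            c.subfield_thickness(shallow, deep, FULL, DiscSpec.foveal(FULL), 3.0, "mean")

    def test_slab_volume_approaches_analytic(self):
        """A flat 200 um slab over the 0.5 mm disc: V -> 0.2 * pi * 0.25 mm^3."""
        layers = _flat_layers(FULL, [400] * 12 + [500])  # 100 voxels = 200 um
        disc = DiscSpec.foveal(FULL)
        ilm, bm = layers["ILM"], layers["BM"]
        v = c.subfield_volume(ilm, bm, FULL, disc, 0.5)
        n_px = c.disc_mask(FULL, disc, 0.5).sum()
        assert v == pytest.approx(0.200 * n_px * FULL.pixel_area_mm2, rel=1e-9)
        assert v == pytest.approx(0.200 * np.pi * 0.25, rel=0.03)

    def test_volume_monotone_in_radius(self):
        layers = _flat_layers(FULL, [400] * 12 + [500])
        disc = DiscSpec.foveal(FULL)
        ilm, bm = layers["ILM"], layers["BM"]
        vols = [c.subfield_volume(ilm, bm, FULL, disc, r) for r in DEFAULT_RADII_MM]
        assert vols[0] < vols[1] < vols[2]


class TestRegistry:
    def test_default_has_105_uniquely_named_entries(self):
        reg = default_registry()
        assert len(reg) == 105
        assert len(set(reg.names)) == 105

    def test_names_round_trip(self):
        for entry in default_registry():
            assert parse_feature_name(entry.name) == entry

    def test_units_assigned(self):
        reg = default_registry()
        units = {e.units for e in reg}
        assert units == {"mm3", "um", "mm"}


class TestExtractFeatures:
    def test_no_cnv_eye_has_zero_pathology_features(self, fixture_cohort):
        eye = next(e for e in fixture_cohort if e.label == "none")
        f = c.extract_features(eye.truth_mask, eye.layers, default_registry())
        path_cols = [n for n in f.index if n.startswith("cscan_")]
        assert len(f) == 105
        assert (f[path_cols] == 0).all()

    def test_planted_ped_volume_matches_truth_bookkeeping(self, fixture_cohort):
        eye = next(e for e in fixture_cohort if e.label == "occult")
        f = c.extract_features(eye.truth_mask, eye.layers, default_registry())
        geom = eye.volume.geometry
        disc = DiscSpec.foveal(geom)
        in_disc = c.disc_mask(geom, disc, 3.0)
        counts = (eye.truth_mask.labels == LABEL_CODES["PED"]).sum(axis=2)
        expected = counts[in_disc].sum() * geom.voxel_volume_mm3
        assert f["cscan_volume_PED_3mm"] == pytest.approx(expected, rel=1e-12)

    def test_radius_monotonicity_across_cohort(self, fixture_truth_features):
        """Every volume/height/width descriptor grows with the disc radius."""
        X, _ = fixture_truth_features
        for kind in ("cscan_volume", "cscan_height", "cscan_width"):
            for cls in c.PATHOLOGY_CLASSES:
                cols = [f"{kind}_{cls}_{r:g}mm" for r in DEFAULT_RADII_MM]
                v = X[cols].to_numpy()
                assert np.all(v[:, 0] <= v[:, 1] + 1e-12)
                assert np.all(v[:, 1] <= v[:, 2] + 1e-12)

    def test_translation_within_central_disc_keeps_volumes(self):
        """Shifting a lesion inside the 0.5 mm disc leaves all volumes unchanged."""
        geom = FULL
        disc = DiscSpec.foveal(geom)
        base = [(64, 256, 500 + k) for k in range(6)]
        shifted = [(64, 256 + 10, 500 + k) for k in range(6)]  # +117 um, in-disc
        m1 = _mask_with_voxels(geom, base)
        m2 = _mask_with_voxels(geom, shifted)
        for r in DEFAULT_RADII_MM:
            assert c.cscan_volume(m1, "PED", disc, r) == c.cscan_volume(
                m2, "PED", disc, r
            )

    def test_unit_scaling_audit(self):
        """Doubling the voxel spacing (and radii) scales each unit correctly."""
        g1 = c.VoxelGeometry(16, 32, 64, (50.0, 100.0, 10.0))
        g2 = c.VoxelGeometry(16, 32, 64, (100.0, 200.0, 20.0))
        rng = np.random.default_rng(0)
        labels = (rng.random(g1.shape) < 0.01).astype(np.uint8) * LABEL_CODES["SRF"]
        m1, m2 = c.PathologyMask(g1, labels), c.PathologyMask(g2, labels.copy())
        d1, d2 = DiscSpec.foveal(g1), DiscSpec.foveal(g2, radii_mm=(1.0, 3.0, 6.0))
        for r1, r2 in zip(DEFAULT_RADII_MM[1:], (3.0, 6.0)):
            assert c.cscan_volume(m2, "SRF", d2, r2) == pytest.approx(
                8 * c.cscan_volume(m1, "SRF", d1, r1)
            )
            assert c.cscan_height(m2, "SRF", d2, r2) == pytest.approx(
                2 * c.cscan_height(m1, "SRF", d1, r1)
            )
            assert c.cscan_width(m2, "SRF", d2, r2) == pytest.approx(
                2 * c.cscan_width(m1, "SRF", d1, r1)
            )
        depths = [10.0 + i for i in range(13)]
        l1, l2 = _flat_layers(g1, depths), _flat_layers(g2, depths)
        t1 = c.subfield_thickness(l1["ILM"], l1["BM"], g1, d1, 1.5, "mean")
        t2 = c.subfield_thickness(l2["ILM"], l2["BM"], g2, d2, 3.0, "mean")
        assert t2 == pytest.approx(2 * t1)

    def test_failure_names_offending_entry(self, fixture_cohort):
        eye = fixture_cohort[0]
        bad = eye.layers.stack().copy()
        bad[0, 0, 0] = bad[12, 0, 0] + 5  # ILM below BM at one position
        layers = c.LayerSet(
            eye.volume.geometry,
            [c.Surface(n, d) for n, d in zip(c.LAYER_NAMES, bad)],
        )
        with pytest.raises(RuntimeError, match="subfield"):
            c.extract_features(eye.truth_mask, layers, default_registry())
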