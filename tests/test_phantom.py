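"""Digital phantom voxelization and CT simulation."""

import math

import numpy as np
import pytest
from scipy import ndimage

from atriamap import phantom as ph

S6 = ndimage.generate_binary_structure(3, 1)


class TestSpecValidation:
    def test_too_coarse_spacing_names_invariant(self):
        with pytest.raises(ValueError, match="spacing"):
            ph.homogeneous_spec(1.0, spacing=0.8)

    def test_wall_thickness_range(self):
        with pytest.raises(ValueError, match="thickness"):
            ph.PhantomSpec(wall_profile=ph.WallProfile.constant(0.1),
                           spacing=(0.05, 0.05, 0.05))

    def test_duplicate_pv_names(self):
        pvs = tuple(ph.PVSpec("RSPV", azimuth_deg=a, attach_height=0.6)
                    for a in (45, 135, 225, 315))
        with pytest.raises(ValueError, match="distinct"):
            ph.PhantomSpec(pv_specs=pvs, spacing=(0.5, 0.5, 0.5))


class TestVoxelization:
    def test_body_extent_matches_design_height(self, coarse_truth, coarse_spec):
        body = np.isin(coarse_truth.labels, (ph.LABEL_LUMEN, ph.LABEL_WALL))
        zs = np.flatnonzero(body.any(axis=(0, 1)))
        n_slices = zs[-1] - zs[0] + 1
        expected = coarse_spec.height / coarse_spec.spacing[2]
        assert abs(n_slices - expected) <= 1

    def test_lumen_single_component_and_wall_seals_it(self, coarse_truth):
        lab = coarse_truth.labels
        _, n = ndimage.label(lab == ph.LABEL_LUMEN, structure=S6)
        assert n == 1
        # above the open basal disc, no lumen->background path avoids wall/PV
        z_base = np.flatnonzero(
            np.isin(lab, (1, 2)).any(axis=(0, 1)))[-1]
        sub = lab[:, :, :z_base + 1]
        open_region = (sub == 0) | (sub == 1)
        cc, _ = ndimage.label(open_region, structure=S6)
        assert cc[0, 0, 0] != cc[tuple(np.argwhere(sub == 1)[0])]

    def test_wall_normal_ray_crosses_enough_voxels(self, coarse_truth, coarse_spec):
        # 2.0 mm wall at 0.5 mm spacing: a horizontal mid-body ray must
        # cross >= 4 wall voxels on each side
        lab = coarse_truth.labels
        zmid = lab.shape[2] // 2
        line = lab[:, lab.shape[1] // 2, zmid]
        runs = np.flatnonzero(line == ph.LABEL_WALL)
        left = runs[runs < lab.shape[0] // 2]
        right = runs[runs >= lab.shape[0] // 2]
        assert len(left) >= 4 and len(right) >= 4

    def test_pv_lumen_cross_section_area(self, coarse_truth, coarse_spec):
        """Tube-lumen voxel volume over a free axial span matches the
        supersampled analytic cylinder within 5%."""
        lab = coarse_truth.labels
        sp = np.asarray(coarse_spec.spacing)
        pv = coarse_spec.pv_specs[0]
        a, u = coarse_spec.pv_frame(pv)
        coords = np.argwhere(lab == ph.LABEL_PV_LUMEN)
        world = (coords + 0.5) * sp + np.asarray(coarse_truth.origin)
        rel = world - a
        axial = rel @ u
        s0, s1 = 4.0, 9.0  # clear of the wall and of the open tube end
        seg_mask = (axial >= s0) & (axial < s1)
        ri = pv.inner_diameter / 2.0
        vol = seg_mask.sum() * float(np.prod(sp))
        # supersampled rasterisation of the same analytic tube segment
        rng = np.arange(-ri - 1, ri + 1, ri / 50.0)
        yy, zz = np.meshgrid(rng, rng, indexing="ij")
        inside = (yy ** 2 + zz ** 2) < ri ** 2
        area = inside.mean() * (rng[-1] - rng[0] + rng[1] - rng[0]) ** 2
        expected = area * (s1 - s0)
        assert vol == pytest.approx(expected, rel=0.05)

    def test_label_count_scaling_with_resolution(self):
        spec_c = ph.homogeneous_spec(2.0, spacing=0.6)
        spec_f = ph.homogeneous_spec(2.0, spacing=0.3)
        nc = np.count_nonzero(ph.voxelize_phantom(spec_c).labels)
        nf = np.count_nonzero(ph.voxelize_phantom(spec_f).labels)
        assert nf / nc == pytest.approx(8.0, rel=0.05)

    def test_lumen_volume_matches_solid_of_revolution(self, h2_truth_fine,
                                                      h2_spec_fine):
        """Voxel-count lumen volume converges to the analytic volume of the
        inner (offset) surface of revolution at 0.25 mm spacing."""
        spec = h2_spec_fine
        pts, zeta = spec.radial_profile.polyline(spec.z_roof_mid, spec.height,
                                                 spec.r_base, ds=0.01)
        # offset the mid-surface inward by t/2 along the curve normal
        t_half = spec.wall_profile.thickness(zeta) / 2.0
        tang = np.gradient(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward in (r, z)
        sign = np.sign(normal[len(normal) // 2, 0]) or 1.0
        inner = pts - sign * normal * t_half[:, None]
        order = np.argsort(inner[:, 1])
        zs, rs = inner[order, 1], np.maximum(inner[order, 0], 0.0)
        analytic = np.trapezoid(math.pi * rs ** 2, zs)
        lumen = np.count_nonzero(h2_truth_fine.labels == ph.LABEL_LUMEN)
        vol = lumen * float(np.prod(spec.spacing))
        assert vol == pytest.approx(analytic, rel=0.02)


class TestSimulateCT:
    def test_zero_degradation_is_exact_lookup(self, coarse_truth):
        params = ph.CTParams(psf_fwhm=0.0, noise_sigma=0.0)
        vol = ph.simulate_ct(coarse_truth, params)
        lut = np.array([params.hu_background, params.hu_lumen, params.hu_wall,
                        params.hu_lumen, params.hu_wall], dtype=np.float32)
        assert np.array_equal(vol.data, lut[coarse_truth.labels])

    def test_same_seed_is_bit_identical(self, coarse_truth):
        a = ph.simulate_ct(coarse_truth, ph.CTParams(rng_seed=7))
        b = ph.simulate_ct(coarse_truth, ph.CTParams(rng_seed=7))
        assert np.array_equal(a.data, b.data)
        c = ph.simulate_ct(coarse_truth, ph.CTParams(rng_seed=8))
        assert not np.array_equal(a.data, c.data)

    def test_blur_preserves_global_mean(self, coarse_truth):
        clean = ph.simulate_ct(coarse_truth, ph.CTParams(psf_fwhm=0, noise_sigma=0))
        blurred = ph.simulate_ct(coarse_truth,
                                 ph.CTParams(psf_fwhm=0.8, noise_sigma=0))
        ref = abs(float(clean.data.mean()))
        assert abs(float(blurred.data.mean()) - float(clean.data.mean())) \
            <= 0.005 * max(ref, 1.0)


class TestGoldStandardMap:
    def test_homogeneous_map_recovers_design_thickness(self, coarse_gold_map,
                                                       coarse_spec):
        from atriamap.metrics import weighted_mean_thickness
        mean = weighted_mean_thickness(coarse_gold_map)
        assert abs(mean - 2.0) <= max(coarse_spec.spacing)

    def test_map_has_four_holes(self, coarse_gold_map):
        from atriamap.metrics import label_pv_holes
        assert len(label_pv_holes(coarse_gold_map)) == 4

    def test_hole_areas_match_oblique_ellipse(self, coarse_gold_map, coarse_spec):
        """Each ostium area ~ pi*r^2/cos(alpha), alpha the angle between the
        tube axis and the local surface normal."""
        from atriamap.metrics import label_pv_holes
        comps = label_pv_holes(coarse_gold_map)
        expected = {}
        for pv in coarse_spec.pv_specs:
            zeta = 1.0 - pv.attach_height
            eps = 1e-4
            dr = (float(coarse_spec.radius(zeta + eps))
                  - float(coarse_spec.radius(zeta - eps)))
            dz = float(coarse_spec.z_of_zeta(zeta + eps)
                       - coarse_spec.z_of_zeta(zeta - eps))
            cos_a = 1.0 / math.hypot(1.0, dr / dz)
            expected[pv.name] = math.pi * (pv.inner_diameter / 2) ** 2 / cos_a
        areas = sorted(c.area for c in comps)
        exp = sorted(expected.values())
        for got, want in zip(areas, exp):
            assert got == pytest.approx(want, rel=0.15)
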