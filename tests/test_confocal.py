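"""Segmentation, signed distance field, layer thickness, signal fractions
and line profiles, each checked against an independent oracle."""

import numpy as np
import pytest

from periscope import confocal
from periscope.confocal import (SegmentationError, line_profile, measure_layer_thickness,
                                normalized_fraction, peripheral_fraction, periphery_mask,
                                segment_lamina, segment_nucleus)
from periscope.grids import BinaryMask3D, VoxelGrid3D
from periscope.synthetic import NucleusParams, _distance_field, generate_nucleus_image


def _true_inner_distance(params, truth, shape):
    """Analytic signed distance to the lamina inner edge on the voxel grid."""
    return _distance_field(shape, params.voxel_size, np.array(truth.center_um),
                           np.array(truth.semi_axes_um)) - params.lamina_shell_thickness


def _dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestSegmentNucleus:
    def test_noiseless_dice(self, noiseless_cell):
        params, channels, truth = noiseless_cell
        mask = segment_nucleus(channels["dna"])
        d = _true_inner_distance(params, truth, mask.shape)
        true_mask = d >= -params.lamina_shell_thickness
        assert _dice(mask.mask, true_mask) >= 0.98

    def test_snr10_dice(self, noisy_cell):
        params, channels, truth = noisy_cell
        mask = segment_nucleus(channels["dna"])
        d = _true_inner_distance(params, truth, mask.shape)
        assert _dice(mask.mask, d >= -params.lamina_shell_thickness) >= 0.95

    def test_all_zero_volume_fails(self):
        grid = VoxelGrid3D(np.zeros((16, 16, 16)), (0.1, 0.1, 0.1), "dna")
        with pytest.raises(SegmentationError):
            segment_nucleus(grid)

    def test_intensity_scale_invariance(self, noisy_cell):
        _, channels, _ = noisy_cell
        m1 = segment_nucleus(channels["dna"])
        scaled = VoxelGrid3D(channels["dna"].intensities * 7.3,
                             channels["dna"].voxel_size, "dna")
        m2 = segment_nucleus(scaled)
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestSegmentLamina:
    def test_center_distance_matches_geometry(self, noiseless_cell):
        params, channels, truth = noiseless_cell
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        dx, dy, dz = params.voxel_size
        ci = (int(truth.center_um[2] / dz), int(truth.center_um[1] / dy),
              int(truth.center_um[0] / dx))
        expected = min(params.semi_axes) - params.lamina_shell_thickness
        assert lam.signed_distance[ci] == pytest.approx(expected, abs=2 * max(dx, dy, dz))

    def test_lamina_voxels_nonpositive(self, noiseless_cell):
        _, channels, _ = noiseless_cell
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        assert (lam.signed_distance[lam.lamina_mask.mask] <= 0).all()
        assert (lam.signed_distance[lam.interior_mask.mask
                                    & ~lam.inner_edge_mask.mask] > 0).all()

    def test_signed_distance_matches_bruteforce_on_small_grid(self):
        # exhaustive nearest-inner-edge-voxel search, anisotropic spacing
        params = NucleusParams(semi_axes=(1.1, 0.95, 0.8), margin=0.25,
                               voxel_size=(0.1, 0.1, 0.08),
                               n_lad_spots=0, n_nonlad_spots=0, snr=None, seed=3)
        channels, _ = generate_nucleus_image(params)
        assert max(channels["dna"].shape) <= 36
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        dz, dy, dx = channels["dna"].sampling_zyx
        edge = np.argwhere(lam.inner_edge_mask.mask) * np.array([dz, dy, dx])
        nzyx = lam.signed_distance.shape
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in nzyx), indexing="ij")
        vox = np.column_stack([zz.ravel() * dz, yy.ravel() * dy, xx.ravel() * dx])
        brute = np.min(np.linalg.norm(vox[:, None, :] - edge[None, :, :], axis=2), axis=1)
        brute = brute.reshape(nzyx)
        signed = np.where(lam.interior_mask.mask, brute, -brute)
        signed[lam.inner_edge_mask.mask] = 0.0
        np.testing.assert_allclose(lam.signed_distance, signed, atol=1e-9)

    def test_open_shell_fails(self):
        vol = np.zeros((20, 20, 20))
        vol[5:15, 5:15, 5:15] = 1.0
        vol[8:12, 8:12, 8:12] = 0.0
        vol[:, 8:13, 8:13] = 0.0  # drill a wide channel to the border
        grid = VoxelGrid3D(vol, (0.1, 0.1, 0.1), "lamina")
        nuc = BinaryMask3D(np.ones_like(vol, bool), (0.1, 0.1, 0.1))
        with pytest.raises(SegmentationError):
            segment_lamina(grid, nuc)


class TestLayerThickness:
    def test_noiseless_default_layer(self, noiseless_cell):
        params, channels, _ = noiseless_cell
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        layer = measure_layer_thickness(channels["h3k9me2"], lam)
        assert layer.method == "measured"
        assert layer.thickness_T == pytest.approx(params.layer_thickness_T, abs=0.1)

    def test_thick_layer_at_snr10(self):
        params = NucleusParams(semi_axes=(2.0, 1.7, 1.4), layer_thickness_T=0.6,
                               n_lad_spots=0, n_nonlad_spots=0, snr=10.0, seed=21)
        channels, _ = generate_nucleus_image(params)
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        layer = measure_layer_thickness(channels["h3k9me2"], lam)
        assert layer.thickness_T == pytest.approx(0.6, abs=0.15)

    def test_degenerate_band_fails(self, noiseless_cell):
        _, channels, _ = noiseless_cell
        nuc = segment_nucleus(channels["dna"])
        lam = segment_lamina(channels["lamina"], nuc)
        # a "band" identical to the lamina shell has no depth
        with pytest.raises(SegmentationError):
            measure_layer_thickness(channels["lamina"], lam)


class TestPeripheralFraction:
    @staticmethod
    def _setup(shape=(16, 16, 16)):
        rng = np.random.default_rng(4)
        vs = (0.1, 0.1, 0.1)
        nucleus = np.zeros(shape, bool)
        nucleus[2:14, 2:14, 2:14] = True
        peri = np.zeros(shape, bool)
        peri[2:14, 2:14, 2:6] = True  # 4/12 of nuclear x-extent
        return rng, vs, BinaryMask3D(nucleus, vs), BinaryMask3D(peri, vs)

    def test_full_containment_gives_one(self):
        rng, vs, nucleus, peri = self._setup()
        img = np.zeros(nucleus.shape)
        img[peri.mask] = rng.uniform(1, 2, peri.mask.sum())
        f = peripheral_fraction(VoxelGrid3D(img, vs, "s"), peri, nucleus,
                                background_subtract=False)
        assert f.fraction == pytest.approx(1.0)

    def test_uniform_signal_proportionality(self):
        _, vs, nucleus, peri = self._setup()
        img = np.ones(nucleus.shape)
        f = peripheral_fraction(VoxelGrid3D(img, vs, "s"), peri, nucleus,
                                background_subtract=False)
        share = (peri.mask & nucleus.mask).sum() / nucleus.mask.sum()
        assert f.fraction == pytest.approx(share, abs=1e-12)

    def test_matches_bruteforce_sums(self):
        rng, vs, nucleus, peri = self._setup()
        img = rng.uniform(0, 5, nucleus.shape)
        f = peripheral_fraction(VoxelGrid3D(img, vs, "s"), peri, nucleus,
                                background_subtract=False)
        masked = sum(img[z, y, x] for z, y, x in np.argwhere(peri.mask & nucleus.mask))
        total = sum(img[z, y, x] for z, y, x in np.argwhere(nucleus.mask))
        assert f.fraction == pytest.approx(masked / total, rel=1e-9)

    def test_monotone_under_mask_dilation(self):
        from scipy import ndimage
        rng, vs, nucleus, peri = self._setup()
        img = rng.uniform(0, 5, nucleus.shape)
        grid = VoxelGrid3D(img, vs, "s")
        f1 = peripheral_fraction(grid, peri, nucleus, background_subtract=False).fraction
        dil = BinaryMask3D(ndimage.binary_dilation(peri.mask), vs)
        f2 = peripheral_fraction(grid, dil, nucleus, background_subtract=False).fraction
        assert f2 >= f1

    def test_nucleus_as_its_own_mask_gives_one(self):
        rng, vs, nucleus, _ = self._setup()
        img = rng.uniform(0.1, 5, nucleus.shape)
        f = peripheral_fraction(VoxelGrid3D(img, vs, "s"), nucleus, nucleus,
                                background_subtract=False)
        assert f.fraction == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng, vs, nucleus, peri = self._setup()
        img = rng.uniform(0, 5, nucleus.shape)
        f1 = peripheral_fraction(VoxelGrid3D(img, vs, "s"), peri, nucleus).fraction
        f2 = peripheral_fraction(VoxelGrid3D(img * 11.0, vs, "s"), peri, nucleus).fraction
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_zero_signal_fails(self):
        _, vs, nucleus, peri = self._setup()
        grid = VoxelGrid3D(np.zeros(nucleus.shape), vs, "s")
        with pytest.raises(ValueError):
            peripheral_fraction(grid, peri, nucleus, background_subtract=False)

    def test_recovery_of_generated_peripheral_share(self):
        # end-to-end: generated share -> segmented masks -> fraction
        for s in (0.3, 0.7):
            params = NucleusParams(semi_axes=(1.8, 1.5, 1.2), n_lad_spots=0,
                                   n_nonlad_spots=0, snr=10.0, seed=31,
                                   signal_share_peripheral=s)
            channels, _ = generate_nucleus_image(params)
            nuc = segment_nucleus(channels["dna"])
            lam = segment_lamina(channels["lamina"], nuc)
            layer = measure_layer_thickness(channels["h3k9me2"], lam)
            peri = periphery_mask(lam, layer, nuc)
            f = peripheral_fraction(channels["signal"], peri, nuc)
            assert f.fraction == pytest.approx(s, abs=0.05)


class TestNormalizedFraction:
    @staticmethod
    def _pf(val, cid="c"):
        return confocal.PeripheralFraction(cid, "ch", "m", masked_signal=val, total_signal=1.0)

    def test_reference_mean_maps_to_one(self):
        groups = {"wt": [self._pf(0.4), self._pf(0.6)], "mut": [self._pf(0.25)]}
        out = normalized_fraction(groups, "wt")
        assert np.mean(out["wt"]) == pytest.approx(1.0)
        assert np.mean(out["mut"]) == pytest.approx(0.5)

    def test_identical_conditions_all_one(self):
        groups = {k: [self._pf(0.3), self._pf(0.5)] for k in ("wt", "a", "b")}
        out = normalized_fraction(groups, "wt")
        for k in out:
            assert np.mean(out[k]) == pytest.approx(1.0)

    def test_empty_reference_fails(self):
        with pytest.raises(ValueError):
            normalized_fraction({"wt": []}, "wt")


class TestLineProfile:
    def test_constant_volume_flat(self):
        grid = VoxelGrid3D(np.full((16, 16, 16), 3.5), (0.1, 0.1, 0.1), "c")
        prof = line_profile([grid], (0.2, 0.2, 0.2), (1.4, 1.4, 1.4), n_samples=20)
        np.testing.assert_allclose(prof.intensities["c"], 3.5)
        assert np.all(np.diff(prof.positions_um) > 0)

    def test_step_transition_located(self):
        vol = np.zeros((16, 16, 32))
        vol[:, :, 16:] = 1.0  # step at x = 1.6 um
        grid = VoxelGrid3D(vol, (0.1, 0.1, 0.1), "c")
        prof = line_profile([grid], (0.3, 0.8, 0.8), (2.9, 0.8, 0.8), n_samples=60)
        crossing = prof.positions_um[np.argmax(prof.intensities["c"] >= 0.5)]
        spacing = prof.positions_um[1] - prof.positions_um[0]
        assert abs((0.3 + crossing) - 1.6) <= spacing + 0.05  # half-voxel offset allowance

    def test_matches_bruteforce_trilinear(self):
        rng = np.random.default_rng(8)
        vol = rng.uniform(0, 10, (12, 14, 16))
        vs = (0.1, 0.12, 0.08)
        grid = VoxelGrid3D(vol, vs, "c")
        p0, p1 = np.array([0.3, 0.4, 0.2]), np.array([1.2, 1.3, 0.8])
        prof = line_profile([grid], p0, p1, n_samples=25)
        for t, val in zip(np.linspace(0, 1, 25), prof.intensities["c"]):
            x, y, z = p0 + t * (p1 - p0)
            fx, fy, fz = x / vs[0] - 0.5, y / vs[1] - 0.5, z / vs[2] - 0.5
            ix, iy, iz = int(fx), int(fy), int(fz)
            wx, wy, wz = fx - ix, fy - iy, fz - iz
            ref = 0.0
            for dz_ in (0, 1):
                for dy_ in (0, 1):
                    for dx_ in (0, 1):
                        w = ((wz if dz_ else 1 - wz) * (wy if dy_ else 1 - wy)
                             * (wx if dx_ else 1 - wx))
                        ref += w * vol[iz + dz_, iy + dy_, ix + dx_]
            assert val == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_endpoints_outside_rejected(self):
        grid = VoxelGrid3D(np.ones((16, 16, 16)), (0.1, 0.1, 0.1), "c")
        with pytest.raises(ValueError):
            line_profile([grid], (0.1, 0.1, 0.1), (5.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            line_profile([grid], (0.1, 0.1, 0.1), (0.1, 0.1, 0.1))
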