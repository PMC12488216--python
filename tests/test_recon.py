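import numpy as np
import pytest

import ewaldhand as eh
from ewaldhand.geometry import GridSpec, Pose
from ewaldhand.optics import OpticsParams, factorize_components
from ewaldhand.recon import (
    KernelSpec,
    VolumeAccumulator,
    accumulate_particle,
    dual_sphere_weights,
    finalize_volume,
    interference_amplitude,
    invert_grid,
    invert_volume,
    reconstruct_particles,
)
from ewaldhand.validate import fsc

from oracles import (
    corrected_components_centered,
    naive_dual_sphere_accumulate,
    naive_planar_insertion,
)


class TestKernelSpec:
    def test_maximum_at_zero_distance(self):
        k = KernelSpec(sigma=0.75)
        d = np.linspace(-3, 3, 61)
        assert np.argmax(k(d)) == 30

    def test_truncated_outside_support(self):
        k = KernelSpec(sigma=0.5, support_radius=1.5)
        assert k(1.6) == 0.0
        assert k(-2.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            KernelSpec(sigma=0.0)
        with pytest.raises(ValueError):
            KernelSpec(sigma=1.0, support_radius=1.5)


class TestDualSphereWeights:
    KERNEL = KernelSpec(sigma=0.75)

    @pytest.mark.parametrize("z_off", [0.1, 0.5, 1.0, 2.0])
    def test_imaginary_weight_vanishes_at_midplane(self, z_off):
        # midway between the spheres the two kernels cancel exactly
        _, _, w = dual_sphere_weights(-z_off, +z_off, self.KERNEL, 1.0, "imaginary")
        assert w == 0.0

    @pytest.mark.parametrize("z_off", [0.1, 0.5, 1.0])
    def test_real_weight_is_twice_single_kernel_at_midplane(self, z_off):
        phi = 0.9
        _, _, w = dual_sphere_weights(-z_off, +z_off, self.KERNEL, phi, "real")
        single = self.KERNEL(z_off) * interference_amplitude(phi, "real")
        assert w == pytest.approx(2.0 * single, rel=1e-12)

    def test_zero_far_from_both_spheres(self):
        for comp in ("real", "imaginary"):
            _, _, w = dual_sphere_weights(10.0, 12.0, self.KERNEL, 1.0, comp)
            assert w == 0.0

    def test_imaginary_magnitude_grows_off_midplane_until_separation(self):
        # scan zeta through the gap for spheres at +-z_off
        z_off = 0.5
        zeta = np.linspace(0.0, z_off + 3 * self.KERNEL.sigma, 40)
        _, _, w = dual_sphere_weights(
            zeta - z_off, zeta + z_off, self.KERNEL, 0.9, "imaginary"
        )
        mag = np.abs(w)
        # rises from exactly zero, then decays once the kernels separate
        assert mag[0] == 0.0
        peak = np.argmax(mag)
        assert 0 < peak < len(zeta) - 1
        assert np.all(np.diff(mag[: peak + 1]) >= 0)

    def test_combined_is_sum_of_sphere_terms(self):
        w_e, w_m, w = dual_sphere_weights(0.3, 1.1, self.KERNEL, 0.7, "real")
        assert w == pytest.approx(w_e + w_m)
        w_e, w_m, w = dual_sphere_weights(0.3, 1.1, self.KERNEL, 0.7, "imaginary")
        assert w == pytest.approx(w_e + w_m)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            interference_amplitude(0.5, "both")


def _tiny_setup(box=16, n_particles=3, seed=0):
    spec = eh.PhantomSpec(box=box, pixel_size=3.0, chirality="right-helix")
    ds = eh.make_dataset(
        spec, n_particles, noise_sigma=0.0, seed=seed,
        optics=OpticsParams(voltage=300.0, pixel_size=3.0, curvature_scale=100.0),
    )
    return ds


class TestAccumulateParticle:
    def test_matches_naive_triple_loop_oracle(self):
        """Gather accumulation against an independent brute-force implementation."""
        ds = _tiny_setup(box=16, n_particles=3, seed=8)
        grid = GridSpec(box=16, pixel_size=3.0)
        kernel = KernelSpec()
        acc_r = VolumeAccumulator.zeros(grid, "real", kernel)
        acc_i = VolumeAccumulator.zeros(grid, "imaginary", kernel)
        ref = [np.zeros((16,) * 3, c) for c in (complex, float, complex, float)]

        for i in range(len(ds.particle_stack)):
            img = ds.particle_stack[i]
            ft = np.fft.fft2(np.fft.ifftshift(img))
            from ewaldhand.optics import compute_wavefront, phase_correct_image

            wf = compute_wavefront(ds.optics, ds.defoci[i], 16)
            comps = factorize_components(phase_correct_image(ft, wf), 3.0)
            accumulate_particle(
                acc_r, acc_i, comps, ds.poses[i],
                ds.optics.with_defocus(ds.defoci[i]), kernel,
            )

            h_c, a_c = corrected_components_centered(
                img, ds.defoci[i], ds.optics.wavelength, 3.0
            )
            pose = ds.poses[i]
            out = naive_dual_sphere_accumulate(
                h_c, a_c, (pose.alpha, pose.beta, pose.gamma), ds.defoci[i],
                ds.optics.wavelength, ds.optics.curvature_wavelength,
                16, 3.0, kernel.sigma, kernel.support_radius,
            )
            for acc_ref, contrib in zip(ref, out):
                acc_ref += contrib

        scale = np.abs(ref[0]).max()
        assert np.abs(acc_r.signal_sum - ref[0]).max() < 1e-10 * scale
        assert np.abs(acc_r.weight_sq_sum - ref[1]).max() < 1e-10 * ref[1].max()
        assert np.abs(acc_i.signal_sum - ref[2]).max() < 1e-10 * max(
            np.abs(ref[2]).max(), scale
        )
        assert np.abs(acc_i.weight_sq_sum - ref[3]).max() < 1e-10 * ref[3].max()

    def test_planar_limit_matches_central_slice_oracle(self):
        """curvature 0: real pipeline = slice insertion; imaginary sums vanish."""
        spec = eh.PhantomSpec(box=16, pixel_size=3.0, chirality="right-helix")
        optics = OpticsParams(voltage=300.0, pixel_size=3.0, curvature_scale=0.0)
        ds = eh.make_dataset(spec, 3, noise_sigma=0.0, seed=9, optics=optics)
        grid = GridSpec(box=16, pixel_size=3.0)
        kernel = KernelSpec()
        acc_r = VolumeAccumulator.zeros(grid, "real", kernel)
        acc_i = VolumeAccumulator.zeros(grid, "imaginary", kernel)
        sig_ref = np.zeros((16,) * 3, complex)
        wsq_ref = np.zeros((16,) * 3)
        from ewaldhand.optics import compute_wavefront, phase_correct_image

        for i in range(3):
            ft = np.fft.fft2(np.fft.ifftshift(ds.particle_stack[i]))
            wf = compute_wavefront(optics, ds.defoci[i], 16)
            comps = factorize_components(phase_correct_image(ft, wf), 3.0)
            accumulate_particle(
                acc_r, acc_i, comps, ds.poses[i],
                optics.with_defocus(ds.defoci[i]), kernel,
            )
            h_c, _ = corrected_components_centered(
                ds.particle_stack[i], ds.defoci[i], optics.wavelength, 3.0
            )
            pose = ds.poses[i]
            s, w = naive_planar_insertion(
                h_c, (pose.alpha, pose.beta, pose.gamma), ds.defoci[i],
                optics.wavelength, 16, 3.0, kernel.sigma, kernel.support_radius,
            )
            sig_ref += s
            wsq_ref += w

        assert np.abs(acc_r.signal_sum - sig_ref).max() < 1e-10 * np.abs(sig_ref).max()
        assert np.abs(acc_r.weight_sq_sum - wsq_ref).max() < 1e-10 * wsq_ref.max()
        # kernel cancellation is exact when the spheres coincide
        assert np.all(acc_i.signal_sum == 0.0)
        assert np.all(acc_i.weight_sq_sum == 0.0)

    def test_zero_antihermite_contributes_nothing_to_imaginary_signal(self):
        ds = _tiny_setup(box=16, n_particles=1, seed=3)
        grid = GridSpec(box=16, pixel_size=3.0)
        acc_r = VolumeAccumulator.zeros(grid, "real")
        acc_i = VolumeAccumulator.zeros(grid, "imaginary")
        ft = np.fft.fft2(ds.particle_stack[0])  # no phase correction: real image
        comps = factorize_components(ft, 3.0)
        assert np.abs(comps.antihermite_ft).max() < 1e-9 * np.abs(ft).max()
        accumulate_particle(acc_r, acc_i, comps, ds.poses[0],
                            ds.optics.with_defocus(ds.defoci[0]))
        assert np.abs(acc_i.signal_sum).max() < 1e-9 * np.abs(acc_r.signal_sum).max()
        assert acc_i.weight_sq_sum.max() > 0.0  # weights accumulate regardless

    def test_linearity_on_repeated_particle(self):
        ds = _tiny_setup(box=16, n_particles=1, seed=4)
        grid = GridSpec(box=16, pixel_size=3.0)
        from ewaldhand.optics import compute_wavefront, phase_correct_image

        ft = np.fft.fft2(np.fft.ifftshift(ds.particle_stack[0]))
        wf = compute_wavefront(ds.optics, ds.defoci[0], 16)
        comps = factorize_components(phase_correct_image(ft, wf), 3.0)
        once_r = VolumeAccumulator.zeros(grid, "real")
        once_i = VolumeAccumulator.zeros(grid, "imaginary")
        twice_r = VolumeAccumulator.zeros(grid, "real")
        twice_i = VolumeAccumulator.zeros(grid, "imaginary")
        op = ds.optics.with_defocus(ds.defoci[0])
        accumulate_particle(once_r, once_i, comps, ds.poses[0], op)
        for _ in range(2):
            accumulate_particle(twice_r, twice_i, comps, ds.poses[0], op)
        assert np.allclose(twice_r.signal_sum, 2 * once_r.signal_sum)
        assert np.allclose(twice_i.weight_sq_sum, 2 * once_i.weight_sq_sum)

    def test_shape_mismatch_rejected(self):
        ds = _tiny_setup(box=16, n_particles=1)
        grid = GridSpec(box=32, pixel_size=3.0)
        acc_r = VolumeAccumulator.zeros(grid, "real")
        acc_i = VolumeAccumulator.zeros(grid, "imaginary")
        comps = factorize_components(np.fft.fft2(ds.particle_stack[0]), 3.0)
        with pytest.raises(ValueError):
            accumulate_particle(acc_r, acc_i, comps, ds.poses[0], ds.optics)

    def test_constant_alpha_shift_rotates_accumulation(self):
        """Adding 90 deg to alpha rotates the reconstruction, without inversion."""
        ds = _tiny_setup(box=16, n_particles=1, seed=6)
        grid = GridSpec(box=16, pixel_size=3.0)
        from ewaldhand.optics import compute_wavefront, phase_correct_image

        ft = np.fft.fft2(np.fft.ifftshift(ds.particle_stack[0]))
        wf = compute_wavefront(ds.optics, ds.defoci[0], 16)
        comps = factorize_components(phase_correct_image(ft, wf), 3.0)
        op = ds.optics.with_defocus(ds.defoci[0])
        base_r = VolumeAccumulator.zeros(grid, "real")
        base_i = VolumeAccumulator.zeros(grid, "imaginary")
        rot_r = VolumeAccumulator.zeros(grid, "real")
        rot_i = VolumeAccumulator.zeros(grid, "imaginary")
        p = ds.poses[0]
        accumulate_particle(base_r, base_i, comps, p, op)
        accumulate_particle(
            rot_r, rot_i, comps, Pose(p.alpha + 90.0, p.beta, p.gamma), op
        )
        # rotating alpha by +90 deg rotates the accumulated transform:
        # acc'(q) = acc(Rz(-90) q), i.e. centered coords (x, y) -> (y, -x),
        # an exact permutation of the centered grid (indices about box//2)
        n = 16
        iy, ix = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        src_y = (n - ix) % n  # y' = -x
        src_x = iy            # x' = +y
        expect = base_r.signal_sum[:, src_y, src_x]
        scale = np.abs(expect).max()
        assert np.abs(rot_r.signal_sum - expect).max() < 1e-9 * scale


class TestFinalizeAndInvert:
    def test_phantom_recovery_at_low_resolution(self, small_dataset, small_maps):
        map_r, _ = small_maps
        curve = fsc(map_r.density, small_dataset.truth_volume, pixel_size=3.0)
        assert np.all(curve.values[1:3] > 0.95)
        assert np.all(curve.values[1:7] > 0.8)

    def test_duplicating_every_particle_leaves_map_unchanged(self):
        ds = _tiny_setup(box=16, n_particles=2, seed=5)
        r1 = reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)
        stack2 = np.concatenate([ds.particle_stack, ds.particle_stack])
        r2 = reconstruct_particles(
            stack2, list(ds.poses) * 2, list(ds.defoci) * 2, ds.optics
        )
        m1 = finalize_volume(r1.acc_real)
        m2 = finalize_volume(r2.acc_real)
        assert np.allclose(m1.density, m2.density, atol=1e-9 * np.abs(m1.density).max())

    def test_huge_weight_floor_zeroes_the_map(self, small_recon):
        vol = finalize_volume(small_recon.acc_real, weight_floor=1e30)
        assert np.all(vol.density == 0.0)

    def test_empty_accumulator_rejected(self):
        grid = GridSpec(box=16, pixel_size=3.0)
        acc = VolumeAccumulator.zeros(grid, "real")
        with pytest.raises(ValueError):
            finalize_volume(acc)
        acc.n_particles = 1  # particles seen but nothing landed in-band
        with pytest.raises(ValueError):
            finalize_volume(acc)

    def test_invert_volume_is_involution(self, small_maps):
        for vol in small_maps:
            back = invert_volume(invert_volume(vol))
            assert np.array_equal(back.density, vol.density)
            assert back.hand == vol.hand

    def test_real_map_histogram_invariant_under_inversion(self, small_maps):
        map_r, _ = small_maps
        inv = invert_volume(map_r)
        assert np.array_equal(
            np.sort(inv.density.ravel()), np.sort(map_r.density.ravel())
        )

    def test_imaginary_map_mean_flips_sign(self, small_maps):
        _, map_i = small_maps
        inv = invert_volume(map_i)
        assert inv.density.mean() == pytest.approx(-map_i.density.mean())

    def test_invert_grid_is_exact_permutation(self, rng):
        arr = rng.normal(size=(8, 8, 8))
        assert np.array_equal(np.sort(invert_grid(arr).ravel()), np.sort(arr.ravel()))
        assert np.array_equal(invert_grid(invert_grid(arr)), arr)


@pytest.fixture(scope="module")
def dataset():
    return _tiny_setup(box=16, n_particles=8, seed=12)


class TestHandednessAlgebra:
    """The central factorization identity: rebuilding the inverted solution
    from the data equals inverting the reconstructed maps."""

    def test_data_route_matches_invert_volume(self, dataset):
        ds = dataset
        res = reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)
        res_inv = reconstruct_particles(
            ds.particle_stack, ds.poses, ds.defoci, ds.optics, invert=True
        )
        for comp in ("real", "imag"):
            direct = finalize_volume(getattr(res_inv, f"acc_{comp}"))
            derived = invert_volume(finalize_volume(getattr(res, f"acc_{comp}")))
            scale = np.abs(derived.density).max()
            assert np.abs(direct.density - derived.density).max() < 1e-10 * scale

    def test_pose_route_matches_invert_volume(self, dataset):
        ds = dataset
        res = reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)
        poses_inv = [eh.invert_pose(p) for p in ds.poses]
        res_inv = reconstruct_particles(
            ds.particle_stack, poses_inv, ds.defoci, ds.optics
        )
        for comp in ("real", "imag"):
            direct = finalize_volume(getattr(res_inv, f"acc_{comp}"))
            derived = invert_volume(finalize_volume(getattr(res, f"acc_{comp}")))
            scale = np.abs(derived.density).max()
            assert np.abs(direct.density - derived.density).max() < 1e-9 * scale

    def test_applying_both_inversions_is_identity(self, dataset):
        ds = dataset
        res = reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)
        poses_inv = [eh.invert_pose(p) for p in ds.poses]
        res_both = reconstruct_particles(
            ds.particle_stack, poses_inv, ds.defoci, ds.optics, invert=True
        )
        m = finalize_volume(res.acc_imag)
        m_both = finalize_volume(res_both.acc_imag)
        assert np.abs(m_both.density - m.density).max() < 1e-9 * np.abs(m.density).max()


class TestKernelOrthogonality:
    def test_single_view_real_imaginary_maps_are_orthogonal(self):
        """Same-view particles (beta = 0, random in-plane gamma): symmetric vs
        antisymmetric z-kernels make the two maps voxel-orthogonal."""
        spec = eh.PhantomSpec(box=16, pixel_size=3.0, chirality="right-helix")
        optics = OpticsParams(voltage=300.0, pixel_size=3.0, curvature_scale=100.0)
        ds = eh.make_dataset(
            spec, 6, noise_sigma=0.0, seed=21, optics=optics,
            orientation="preferred", beta_preferred=0.0,
        )
        res = reconstruct_particles(ds.particle_stack, ds.poses, ds.defoci, ds.optics)
        m_r = finalize_volume(res.acc_real).density
        m_i = finalize_volume(res.acc_imag).density
        overlap = np.abs(np.sum(m_r * m_i))
        norm = np.linalg.norm(m_r) * np.linalg.norm(m_i)
        assert overlap < 1e-6 * norm
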