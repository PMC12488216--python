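"""Gather-based dual-sphere reconstruction of the real and imaginary maps.

For every particle the reconstruction grid is traversed (gather method):
each grid point is rotated into the particle frame, giving an in-plane
frequency k, a height zeta, and signed distances to the Ewald sphere
(zeta - zeta_E) and to its Friedel mate (zeta + zeta_E) with
zeta_E = lambda_c * |k|^2 / 2.  The Hermite (real-component) transform is
sampled at k and deposited with weight

    w_R = sin(Phi) * [K(d_ewald) + K(d_mate)]          (additive kernels)

and the anti-Hermite transform with

    w_I = -sin(Phi) * [K(d_ewald) - K(d_mate)]         (opposite signs),

where K is a truncated Gaussian kernel and Phi = 2*phi(k) is the
interference phase between the two spheres (phi the defocus wavefront
phase).  +-sin(Phi) is the CTF of the phase-corrected image in the planar
approximation; it is the matched amplitude of the structure-carrying
channel of each component (the symmetric sum of the two sphere samples for
H, their antisymmetric difference for A).  Two running sums are kept per
component: sum(w * value) and sum(w^2).

Maps and their inverted-solution counterparts obey the factorization
identity: the real map inverts through the origin unchanged, the imaginary
map inverts *and* flips sign, so the inverted solution is obtained from the
original accumulators at no extra cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import GridSpec, Pose, grid_freq_table, map_grid_points
from .optics import (
    ComponentImages,
    OpticsParams,
    compute_wavefront,
    factorize_components,
    phase_correct_image,
)

__all__ = [
    "KernelSpec",
    "VolumeAccumulator",
    "ReconstructedVolume",
    "ReconResult",
    "interference_amplitude",
    "dual_sphere_weights",
    "accumulate_particle",
    "finalize_volume",
    "invert_volume",
    "invert_grid",
    "reconstruct_particles",
    "shell_index_grid",
    "ft3_centered",
    "ift3_centered",
]

#: Calibration constant fixing which imaginary-map sign corresponds to the
#: correct-hand solution (the "detector handedness" calibration the method
#: requires).  It folds together the FFT sign convention, the weak-phase i,
#: and the sign of the kernel difference; it is set once so that a
#: self-consistent dataset (true poses, true defoci) yields a positive
#: I-R FSC, after which the wrong-hand solution of any dataset reads
#: negative.
HANDEDNESS_SIGN = +1.0


# ---------------------------------------------------------------------------
# small FFT / grid helpers (centered layouts)

def ft3_centered(vol: np.ndarray) -> np.ndarray:
    """3D FFT with both real-space origin and k=0 at index box//2."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def ift3_centered(ft: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ft)))


def invert_grid(arr: np.ndarray) -> np.ndarray:
    """Point inversion through the centre voxel (index box//2, even grids)."""
    rev = arr[(slice(None, None, -1),) * arr.ndim]
    return np.roll(rev, shift=(1,) * arr.ndim, axis=tuple(range(arr.ndim)))


def shell_index_grid(box: int) -> np.ndarray:
    """Integer shell index per voxel of a centered cubic Fourier grid.

    Shell s collects voxels with round(|k|) == s in voxel units, ties at
    half-integers rounded up.
    """
    ax = np.arange(box) - box // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    return np.floor(r + 0.5).astype(np.int32)


# ---------------------------------------------------------------------------
# kernel and weights

@dataclass(frozen=True)
class KernelSpec:
    """Truncated Gaussian interpolation kernel in reciprocal-space voxels."""

    sigma: float = 0.75
    support_radius: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("kernel sigma must be positive")
        if self.support_radius is None:
            object.__setattr__(self, "support_radius", 3.0 * self.sigma)
        if self.support_radius < 2.0 * self.sigma:
            raise ValueError("support_radius must be at least 2 sigma")

    def __call__(self, dist_voxels: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dist_voxels, dtype=float)
        val = np.exp(-0.5 * (d / self.sigma) ** 2)
        return np.where(np.abs(d) <= self.support_radius, val, 0.0)


def interference_amplitude(phi: np.ndarray | float, component: str):
    """Ewald--Friedel interference amplitude for one component.

    ``phi`` is the defocus wavefront phase at the in-plane frequency; the
    phase difference between the two sidebands is Phi = 2*phi.  Writing the
    corrected transform's components as H = a F+ + conj(a) F- and
    A = b F+ - conj(b) F- with a = i cos(phi) e^{-i phi} and
    b = -sin(phi) e^{-i phi}, the structure-carrying coefficients are
    Re(a) = sin(Phi)/2 for the sum channel of H and Re(b) = -sin(Phi)/2 for
    the difference channel of A: both interference amplitudes are the CTF
    of the corrected image in the planar approximation, up to sign.
    Isolated here so the functional form can be swapped wholesale.
    """
    big_phi = 2.0 * np.asarray(phi, dtype=float)
    if component == "real":
        out = np.sin(big_phi)
    elif component == "imaginary":
        out = -np.sin(big_phi)
    else:
        raise ValueError(f"unknown component {component!r}")
    return float(out) if out.ndim == 0 else out


def dual_sphere_weights(
    z_dist_ewald,
    z_dist_mate,
    kernel: KernelSpec,
    interference_phase,
    component: str,
):
    """Kernel weights from both spheres plus the interference amplitude.

    Distances are in reciprocal voxels (consistent with ``kernel.sigma``).
    Real component: the two kernel evaluations enter with the same sign and
    add; imaginary component: opposite signs, so the combined weight is
    exactly zero midway between the spheres.  Returns
    ``(weight_ewald, weight_mate, combined)``.
    """
    amp = interference_amplitude(interference_phase, component)
    k_e = kernel(z_dist_ewald)
    k_m = kernel(z_dist_mate)
    if component == "real":
        w_e, w_m = amp * k_e, amp * k_m
        return w_e, w_m, w_e + w_m
    w_e, w_m = amp * k_e, -amp * k_m
    return w_e, w_m, w_e + w_m


# ---------------------------------------------------------------------------
# accumulation

@dataclass
class VolumeAccumulator:
    """Running sums for one component's reconstruction (centered grids)."""

    signal_sum: np.ndarray  # complex, sum of weight * sampled value
    weight_sq_sum: np.ndarray  # real, sum of weight^2
    component: str  # 'real' | 'imaginary'
    n_particles: int
    grid: GridSpec
    kernel: KernelSpec

    @classmethod
    def zeros(cls, grid: GridSpec, component: str, kernel: KernelSpec | None = None):
        kernel = kernel or KernelSpec()
        shape = (grid.box,) * 3
        return cls(
            signal_sum=np.zeros(shape, dtype=np.complex128),
            weight_sq_sum=np.zeros(shape, dtype=np.float64),
            component=component,
            n_particles=0,
            grid=grid,
            kernel=kernel,
        )

    def merged(self, other: "VolumeAccumulator") -> "VolumeAccumulator":
        if self.component != other.component or self.grid != other.grid:
            raise ValueError("cannot merge accumulators of different kind")
        return VolumeAccumulator(
            signal_sum=self.signal_sum + other.signal_sum,
            weight_sq_sum=self.weight_sq_sum + other.weight_sq_sum,
            component=self.component,
            n_particles=self.n_particles + other.n_particles,
            grid=self.grid,
            kernel=self.kernel,
        )

    def shell_weight_sums(self) -> np.ndarray:
        """Per-shell totals of the weight-squared sum (length box//2 + 1)."""
        s = shell_index_grid(self.grid.box)
        nsh = self.grid.box // 2 + 1
        mask = s < nsh
        return np.bincount(
            s[mask].ravel(), weights=self.weight_sq_sum[mask].ravel(), minlength=nsh
        )

    def shell_participation(self) -> np.ndarray:
        """Effective voxel count per shell from the weight distribution.

        Participation ratio (sum w)^2 / sum w^2 of the per-voxel
        accumulated weights within each shell.  Uniform angular coverage
        gives the filled-voxel count; preferred-orientation data, whose
        weight concentrates on a thin annulus of the shell, give a much
        smaller count — the correct degrees-of-freedom for correlation
        significance under anisotropic coverage.
        """
        s = shell_index_grid(self.grid.box)
        nsh = self.grid.box // 2 + 1
        mask = s < nsh
        lab = s[mask].ravel()
        w = self.weight_sq_sum[mask].ravel()
        tot = np.bincount(lab, weights=w, minlength=nsh)
        tot2 = np.bincount(lab, weights=w**2, minlength=nsh)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(tot2 > 0, tot**2 / np.maximum(tot2, 1e-300), 0.0)
        return pr


def _bilinear_sample(arr: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2D array at fractional indices (u=row, v=col)."""
    u0 = np.floor(u).astype(np.intp)
    v0 = np.floor(v).astype(np.intp)
    fu = u - u0
    fv = v - v0
    a00 = arr[u0, v0]
    a01 = arr[u0, v0 + 1]
    a10 = arr[u0 + 1, v0]
    a11 = arr[u0 + 1, v0 + 1]
    return (
        a00 * (1 - fu) * (1 - fv)
        + a01 * (1 - fu) * fv
        + a10 * fu * (1 - fv)
        + a11 * fu * fv
    )


def accumulate_particle(
    acc_real: VolumeAccumulator,
    acc_imag: VolumeAccumulator,
    components: ComponentImages,
    pose: Pose,
    optics: OpticsParams,
    kernel: KernelSpec | None = None,
) -> None:
    """Gather one particle's Hermite/anti-Hermite data into the accumulators.

    Only grid points within the particle's slab (tangent plane +- maximum
    sphere offset + kernel support) receive contributions.  The particle's
    defocus is taken from ``optics.base_defocus_z``.
    """
    grid = acc_real.grid
    kernel = kernel or acc_real.kernel
    n = grid.box
    if components.box_size != n:
        raise ValueError(
            f"component box {components.box_size} != reconstruction box {n}"
        )
    if components.pixel_size != grid.pixel_size:
        raise ValueError("pixel size mismatch between components and grid")

    lam_c = optics.curvature_wavelength
    defocus = optics.base_defocus_z
    dk = grid.dk
    supp_inv_a = kernel.support_radius * dk  # kernel support in A^-1

    qvecs = grid_freq_table(grid)
    geo = map_grid_points(qvecs, pose, lam_c)
    kx, ky, zeta = geo["kx"], geo["ky"], geo["zeta"]
    k2 = kx**2 + ky**2

    # slab + band mask; leave one-voxel margin for bilinear sampling
    k_max = (n // 2 - 2) * dk
    near = (np.abs(geo["d_ewald"]) <= supp_inv_a) | (np.abs(geo["d_mate"]) <= supp_inv_a)
    mask = near & (k2 <= k_max**2)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        acc_real.n_particles += 1
        acc_imag.n_particles += 1
        return

    kxm, kym = kx[idx], ky[idx]
    d_e = geo["d_ewald"][idx] / dk  # reciprocal voxels
    d_m = geo["d_mate"][idx] / dk
    phi = 2.0 * np.pi * (-defocus * optics.wavelength * (kxm**2 + kym**2) / 2.0)

    _, _, w_r = dual_sphere_weights(d_e, d_m, kernel, phi, "real")
    _, _, w_i = dual_sphere_weights(d_e, d_m, kernel, phi, "imaginary")

    # sample the centered 2D transforms at the mapped in-plane coordinates
    half = n // 2
    u = kym / dk + half  # row index <-> ky
    v = kxm / dk + half  # col index <-> kx
    h_c = np.fft.fftshift(components.hermite_ft)
    a_c = np.fft.fftshift(components.antihermite_ft)
    h_s = _bilinear_sample(h_c, u, v)
    a_s = _bilinear_sample(a_c, u, v)

    flat_r = acc_real.signal_sum.reshape(-1)
    flat_rw = acc_real.weight_sq_sum.reshape(-1)
    flat_i = acc_imag.signal_sum.reshape(-1)
    flat_iw = acc_imag.weight_sq_sum.reshape(-1)
    flat_r[idx] += w_r * h_s
    flat_rw[idx] += w_r**2
    flat_i[idx] += w_i * a_s
    flat_iw[idx] += w_i**2
    acc_real.n_particles += 1
    acc_imag.n_particles += 1


# ---------------------------------------------------------------------------
# finalization and inversion

@dataclass
class ReconstructedVolume:
    """A real-space map finalized from one component's accumulator."""

    density: np.ndarray  # real 3D grid, centered
    component: str  # 'real' | 'imaginary'
    hand: str  # 'as_given' | 'inverted'
    grid: GridSpec
    per_shell_snr: np.ndarray | None = None


def finalize_volume(
    acc: VolumeAccumulator, weight_floor: float = 1e-3
) -> ReconstructedVolume:
    """Divide the signal sum by the weight-squared sum and transform back.

    The division is regularized per shell: the denominator is floored at
    ``weight_floor`` times the shell median of positive weights, and voxels
    whose accumulated weight sits below that floor are zeroed.
    """
    if acc.n_particles < 1:
        raise ValueError("empty reconstruction: no particles accumulated")
    wsq = acc.weight_sq_sum
    if not np.any(wsq > 0):
        raise ValueError("empty reconstruction: all weights zero")

    box = acc.grid.box
    shells = shell_index_grid(box)
    nsh = box // 2 + 1
    floor_per_shell = np.zeros(nsh)
    for s in range(nsh):
        vals = wsq[(shells == s) & (wsq > 0)]
        if vals.size:
            floor_per_shell[s] = weight_floor * np.median(vals)
    floor_map = np.where(shells < nsh, floor_per_shell[np.minimum(shells, nsh - 1)], 0.0)

    live = (wsq >= floor_map) & (floor_map > 0) & (shells < nsh)
    denom = np.where(live, np.maximum(wsq, floor_map), 1.0)
    fgrid = np.where(live, acc.signal_sum, 0.0) / denom

    # Both accumulators are Hermitian about the origin: the real component
    # because additive weights pair with conj(H(-k)) = H(k); the imaginary
    # component because the kernel difference flips sign at -q exactly when
    # the anti-Hermite data conjugate-negates.  Either inverse transform is
    # therefore real; the curvature (Delta-z) signal of the imaginary
    # component lives in that real map.
    real_space = ift3_centered(fgrid)
    if acc.component == "real":
        density = np.real(real_space)
    else:
        density = HANDEDNESS_SIGN * np.real(real_space)
    return ReconstructedVolume(
        density=density, component=acc.component, hand="as_given", grid=acc.grid
    )


def invert_volume(vol: ReconstructedVolume) -> ReconstructedVolume:
    """The inverted 3D solution, derived from the map itself.

    Real component: point inversion only.  Imaginary component: point
    inversion and a sign flip — the factorization property that powers the
    handedness readout.
    """
    density = invert_grid(vol.density)
    if vol.component == "imaginary":
        density = -density
    return ReconstructedVolume(
        density=density,
        component=vol.component,
        hand="inverted" if vol.hand == "as_given" else "as_given",
        grid=vol.grid,
        per_shell_snr=None if vol.per_shell_snr is None else vol.per_shell_snr.copy(),
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline

@dataclass
class ReconResult:
    """Accumulators and half-set splits for one dataset reconstruction."""

    half_real: tuple[VolumeAccumulator, VolumeAccumulator]
    half_imag: tuple[VolumeAccumulator, VolumeAccumulator]
    grid: GridSpec
    kernel: KernelSpec

    @property
    def acc_real(self) -> VolumeAccumulator:
        return self.half_real[0].merged(self.half_real[1])

    @property
    def acc_imag(self) -> VolumeAccumulator:
        return self.half_imag[0].merged(self.half_imag[1])


def reconstruct_particles(
    images: Sequence[np.ndarray] | np.ndarray,
    poses: Sequence[Pose],
    defoci: Iterable[float],
    optics: OpticsParams,
    kernel: KernelSpec | None = None,
    invert: bool = False,
) -> ReconResult:
    """Full pipeline: FFT, phase-correct, factorize and gather every particle.

    Particles are split into half-sets by even/odd index (deterministic,
    seed-free) for half-map FSC estimation.  ``invert=True`` builds the
    inverted solution directly from the data (equivalent to resetting
    gamma -> gamma + 180 deg); it exists for testing the factorization
    identity — in production the inverted maps come free via
    :func:`invert_volume`.
    """
    images = np.asarray(images)
    n_img, box, _ = images.shape
    grid = GridSpec(box=box, pixel_size=optics.pixel_size)
    kernel = kernel or KernelSpec()
    halves_r = [VolumeAccumulator.zeros(grid, "real", kernel) for _ in range(2)]
    halves_i = [VolumeAccumulator.zeros(grid, "imaginary", kernel) for _ in range(2)]

    defoci = list(defoci)
    for i in range(n_img):
        ft = np.fft.fft2(np.fft.ifftshift(images[i]))
        wavefront = compute_wavefront(optics, defoci[i], box)
        corrected = phase_correct_image(ft, wavefront)
        comps = factorize_components(corrected, pixel_size=optics.pixel_size)
        if invert:
            comps = comps.inverted_solution()
        accumulate_particle(
            halves_r[i % 2],
            halves_i[i % 2],
            comps,
            poses[i],
            optics.with_defocus(defoci[i]),
            kernel,
        )
    return ReconResult(
        half_real=(halves_r[0], halves_r[1]),
        half_imag=(halves_i[0], halves_i[1]),
        grid=grid,
        kernel=kernel,
    )
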