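"""Independent brute-force reference implementations used by the tests.

Everything here is written from the model definition with plain loops and
its own rotation/interpolation/kernel code, deliberately sharing no code
path with the package's vectorized gather, so agreement is evidence and
not tautology.
"""

import math

import numpy as np
from scipy.spatial.transform import Rotation


def euler_matrix(alpha, beta, gamma):
    return Rotation.from_euler("ZYZ", [alpha, beta, gamma], degrees=True).as_matrix()


def gaussian_kernel(d, sigma, support):
    if abs(d) > support:
        return 0.0
    return math.exp(-0.5 * (d / sigma) ** 2)


def bilinear(arr, row, col):
    r0, c0 = int(math.floor(row)), int(math.floor(col))
    fr, fc = row - r0, col - c0
    return (
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0, c0 + 1] * (1 - fr) * fc
        + arr[r0 + 1, c0] * fr * (1 - fc)
        + arr[r0 + 1, c0 + 1] * fr * fc
    )


def naive_dual_sphere_accumulate(
    hermite_c, anti_c, pose_deg, defocus, wavelength, curvature_wavelength,
    box, pixel_size, sigma, support,
):
    """Triple-loop gather over every reconstruction voxel of one particle.

    ``hermite_c``/``anti_c`` are the centered 2D component transforms.
    Returns (signal_real, wsq_real, signal_imag, wsq_imag) on centered
    3D grids.
    """
    half = box // 2
    dk = 1.0 / (box * pixel_size)
    rot = euler_matrix(*pose_deg)
    sig_r = np.zeros((box, box, box), dtype=complex)
    wsq_r = np.zeros((box, box, box))
    sig_i = np.zeros((box, box, box), dtype=complex)
    wsq_i = np.zeros((box, box, box))
    k_max = (half - 2) * dk

    for iz in range(box):
        for iy in range(box):
            for ix in range(box):
                q = np.array(
                    [(ix - half) * dk, (iy - half) * dk, (iz - half) * dk]
                )
                p = rot.T @ q
                kx, ky, zeta = p
                k2 = kx * kx + ky * ky
                if k2 > k_max * k_max:
                    continue
                zoff = curvature_wavelength * k2 / 2.0
                d_e = (zeta - zoff) / dk
                d_m = (zeta + zoff) / dk
                if abs(d_e) > support and abs(d_m) > support:
                    continue
                ke = gaussian_kernel(d_e, sigma, support)
                km = gaussian_kernel(d_m, sigma, support)
                phi = 2.0 * math.pi * (-defocus * wavelength * k2 / 2.0)
                w_r = math.sin(2.0 * phi) * (ke + km)
                w_i = -math.sin(2.0 * phi) * (ke - km)
                row = ky / dk + half
                col = kx / dk + half
                h = bilinear(hermite_c, row, col)
                a = bilinear(anti_c, row, col)
                sig_r[iz, iy, ix] += w_r * h
                wsq_r[iz, iy, ix] += w_r * w_r
                sig_i[iz, iy, ix] += w_i * a
                wsq_i[iz, iy, ix] += w_i * w_i
    return sig_r, wsq_r, sig_i, wsq_i


def naive_planar_insertion(
    hermite_c, pose_deg, defocus, wavelength, box, pixel_size, sigma, support
):
    """Central-slice insertion with a Gaussian z-kernel and planar CTF weight.

    The flat-sphere reference: every reconstruction voxel gathers the image
    transform at its rotated in-plane coordinate, weighted by
    sin(2*phi) * 2*K(zeta) — what the dual-sphere scheme must reduce to
    when the curvature wavelength is zero.
    """
    half = box // 2
    dk = 1.0 / (box * pixel_size)
    rot = euler_matrix(*pose_deg)
    sig = np.zeros((box, box, box), dtype=complex)
    wsq = np.zeros((box, box, box))
    k_max = (half - 2) * dk
    for iz in range(box):
        for iy in range(box):
            for ix in range(box):
                q = np.array(
                    [(ix - half) * dk, (iy - half) * dk, (iz - half) * dk]
                )
                p = rot.T @ q
                kx, ky, zeta = p
                k2 = kx * kx + ky * ky
                if k2 > k_max * k_max:
                    continue
                dzv = zeta / dk
                if abs(dzv) > support:
                    continue
                kz = gaussian_kernel(dzv, sigma, support)
                phi = 2.0 * math.pi * (-defocus * wavelength * k2 / 2.0)
                w = math.sin(2.0 * phi) * 2.0 * kz
                h = bilinear(hermite_c, ky / dk + half, kx / dk + half)
                sig[iz, iy, ix] += w * h
                wsq[iz, iy, ix] += w * w
    return sig, wsq


def corrected_components_centered(image, defocus, wavelength, pixel_size):
    """Phase-correct and factorize one image, independently of the package.

    Returns centered Hermite and anti-Hermite transforms.
    """
    box = image.shape[0]
    ft = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))
    f1 = np.fft.fftshift(np.fft.fftfreq(box, d=pixel_size))
    ky, kx = np.meshgrid(f1, f1, indexing="ij")
    phi = 2.0 * np.pi * (-defocus * wavelength * (kx**2 + ky**2) / 2.0)
    corrected = ft * np.exp(1j * phi)
    half = box // 2
    mirrored = np.full_like(corrected, np.nan)
    for iy in range(box):
        for ix in range(box):
            my, mx = (2 * half - iy) % box, (2 * half - ix) % box
            mirrored[iy, ix] = np.conj(corrected[my, mx])
    hermite = 0.5 * (corrected + mirrored)
    anti = 0.5 * (corrected - mirrored)
    return hermite, anti
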