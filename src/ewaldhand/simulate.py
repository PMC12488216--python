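"""Synthetic chiral phantoms and forward-modelled particle images.

The forward model is the weak-phase, dual-sphere image used by the
reconstruction algebra: for a particle at pose R with defocus z the image
transform at in-plane frequency k is

    I(k) = i e^{-i phi} F(R p+) - i e^{+i phi} F(R p-),

with p+- = (kx, ky, +-zeta_E), zeta_E = lambda_c |k|^2/2, and
phi = -pi z lambda |k|^2 the wavefront phase.  The |Fe|^2 term of the
intensity is dropped (weak-phase regime), which keeps the model linear so
reconstructions have a known ground truth.  Noise is white Gaussian in
real space.

``OpticsParams.curvature_scale`` exaggerates lambda_c only, so desk-scale
datasets (hundreds of particles) carry an imaginary-component signal that
real data would only show with hundreds of thousands of particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GridSpec, Pose, rotation_matrix
from .optics import OpticsParams
from .recon import ft3_centered, invert_grid

__all__ = [
    "Blob",
    "PhantomSpec",
    "SyntheticDataset",
    "build_phantom",
    "forward_project",
    "make_dataset",
    "random_poses",
    "DEFAULT_STUDY",
]

#: Frozen desk-scale study conditions used by the CLI defaults and the
#: acceptance experiments: a 48^3 box at 3 A/pixel holding a chiral helix
#: wider than the depth of focus at Nyquist once curvature is exaggerated
#: 100x, moderate noise (sigma = half the per-image signal RMS), and a
#: defocus spread typical of a cryoEM collection (0.5-2.5 um), wide enough
#: that the interference phase decorrelates across particles at mid
#: resolution.
DEFAULT_STUDY = {
    "box": 48,
    "pixel_size": 3.0,
    "voltage": 300.0,
    "curvature_scale": 100.0,
    "n_particles": 600,
    "defocus_range": (5000.0, 25000.0),
    "noise_sigma": 0.5,
    "noise_relative": True,
}


@dataclass(frozen=True)
class Blob:
    center: tuple[float, float, float]  # Angstrom, relative to box centre
    sigma: float  # Angstrom
    amplitude: float = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Sum-of-Gaussian-blobs phantom; helical blob paths give chirality.

    Helix geometry defaults scale with the box (radius 5/16 of the box
    extent, height 5/8, blob width 1/24) so the phantom fills the field of
    view at any box size; at the 48-voxel, 3 A/pixel study box these are
    45, 90 and 6 Angstrom.
    """

    box: int = 48
    pixel_size: float = 3.0
    chirality: str = "right-helix"  # 'right-helix' | 'left-helix' | 'achiral'
    helix_radius: float | None = None  # Angstrom
    helix_height: float | None = None  # Angstrom, full z extent of the path
    turns: float = 1.5
    n_blobs: int = 40
    blob_sigma: float | None = None  # Angstrom
    amplitude: float = 1.0
    extra_blobs: tuple[Blob, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        extent = self.box * self.pixel_size
        if self.helix_radius is None:
            object.__setattr__(self, "helix_radius", extent * 45.0 / 144.0)
        if self.helix_height is None:
            object.__setattr__(self, "helix_height", extent * 90.0 / 144.0)
        if self.blob_sigma is None:
            object.__setattr__(self, "blob_sigma", extent / 24.0)

    def blob_list(self) -> list[Blob]:
        blobs = list(self.extra_blobs)
        if self.chirality == "achiral":
            blobs.append(Blob((0.0, 0.0, 0.0), sigma=self.helix_radius / 2.0,
                              amplitude=self.amplitude))
            return blobs
        handed = {"right-helix": +1.0, "left-helix": -1.0}
        try:
            sign = handed[self.chirality]
        except KeyError:
            raise ValueError(f"unknown chirality {self.chirality!r}") from None
        for t in np.linspace(0.0, 1.0, self.n_blobs):
            ang = sign * 2.0 * math.pi * self.turns * t
            blobs.append(
                Blob(
                    (
                        self.helix_radius * math.cos(ang),
                        self.helix_radius * math.sin(ang),
                        self.helix_height * (t - 0.5),
                    ),
                    sigma=self.blob_sigma,
                    amplitude=self.amplitude,
                )
            )
        return blobs


def build_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom on a centered cubic grid (z, y, x order).

    A chiral phantom is self-checked at generation: its correlation with
    its own point inversion must stay below 0.9, otherwise the handedness
    experiments would be meaningless.
    """
    n, px = spec.box, spec.pixel_size
    half_extent = (n // 2) * px
    ax = (np.arange(n) - n // 2) * px
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((n, n, n))
    for blob in spec.blob_list():
        cx, cy, cz = blob.center
        if max(abs(cx), abs(cy), abs(cz)) + 3.0 * blob.sigma > half_extent:
            raise ValueError(f"blob at {blob.center} does not fit inside the box")
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        vol += blob.amplitude * np.exp(-0.5 * r2 / blob.sigma**2)

    if spec.chirality != "achiral":
        mirrored = invert_grid(vol)
        cc = float(np.corrcoef(vol.ravel(), mirrored.ravel())[0, 1])
        if cc >= 0.9:
            raise ValueError(
                f"phantom is insufficiently chiral (inversion correlation {cc:.3f})"
            )
    return vol


def _trilinear_sample(arr: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Trilinear interpolation at fractional voxel coords (x->axis2, z->axis0)."""
    x0 = np.floor(x).astype(np.intp)
    y0 = np.floor(y).astype(np.intp)
    z0 = np.floor(z).astype(np.intp)
    fx, fy, fz = x - x0, y - y0, z - z0
    out = np.zeros(x.shape, dtype=arr.dtype)
    for dz in (0, 1):
        wz = fz if dz else 1 - fz
        for dy in (0, 1):
            wy = fy if dy else 1 - fy
            for dx in (0, 1):
                wx = fx if dx else 1 - fx
                out = out + arr[z0 + dz, y0 + dy, x0 + dx] * (wz * wy * wx)
    return out


def _project_ft(
    truth_ft_centered: np.ndarray,
    pose: Pose,
    defocus: float,
    optics: OpticsParams,
    grid: GridSpec,
) -> np.ndarray:
    """Noise-free image transform on the centered 2D grid."""
    n = grid.box
    half = n // 2
    dk = grid.dk
    f1 = (np.arange(n) - half) * dk
    ky, kx = np.meshgrid(f1, f1, indexing="ij")
    k2 = kx**2 + ky**2
    zeta = optics.curvature_wavelength * k2 / 2.0

    rot = rotation_matrix(pose)
    img_ft = np.zeros((n, n), dtype=np.complex128)
    k_max = (half - 2) * dk
    band = k2 <= k_max**2

    phi = 2.0 * np.pi * (-defocus * optics.wavelength * k2 / 2.0)
    for sign, ctf_phase, pref in ((+1.0, -1.0, 1j), (-1.0, +1.0, -1j)):
        p = np.stack([kx, ky, sign * zeta], axis=-1)  # particle frame
        q = p @ rot.T  # reconstruction frame
        xs = q[..., 0] / dk + half
        ys = q[..., 1] / dk + half
        zs = q[..., 2] / dk + half
        samp = np.zeros((n, n), dtype=np.complex128)
        samp[band] = _trilinear_sample(
            truth_ft_centered, xs[band], ys[band], zs[band]
        )
        img_ft += pref * np.exp(1j * ctf_phase * phi) * samp
    return img_ft


def forward_project(
    truth: np.ndarray,
    pose: Pose,
    defocus: float,
    optics: OpticsParams,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one particle image (real 2D array, particle centered)."""
    n = truth.shape[0]
    grid = GridSpec(box=n, pixel_size=optics.pixel_size)
    ftc = ft3_centered(truth)
    img_ft = _project_ft(ftc, pose, defocus, optics, grid)
    img = np.real(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(img_ft))))
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img


def random_poses(
    n: int,
    rng: np.random.Generator,
    mode: str = "uniform",
    beta_preferred: float = 60.0,
    alpha_preferred: float = 0.0,
) -> list[Pose]:
    """Draw particle poses.

    'uniform': alpha, gamma ~ U(0, 360), cos(beta) ~ U(-1, 1) — uniform over
    SO(3), so beta has the sin(beta) marginal.  'preferred': fixed viewing
    direction (alpha, beta constant), random in-plane gamma — the
    preferred-orientation extreme used for the null calibration.
    """
    if mode == "uniform":
        alphas = rng.uniform(0.0, 360.0, n)
        betas = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
        gammas = rng.uniform(0.0, 360.0, n)
    elif mode == "preferred":
        alphas = np.full(n, alpha_preferred)
        betas = np.full(n, beta_preferred)
        gammas = rng.uniform(0.0, 360.0, n)
    else:
        raise ValueError(f"unknown pose mode {mode!r}")
    return [Pose(a, b, g) for a, b, g in zip(alphas, betas, gammas)]


@dataclass
class SyntheticDataset:
    particle_stack: np.ndarray  # (n, box, box) real images
    poses: list[Pose]
    defoci: np.ndarray  # Angstrom
    optics: OpticsParams
    truth_volume: np.ndarray
    truth_hand: str  # chirality label of the phantom as built
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        if not (len(self.particle_stack) == len(self.poses) == len(self.defoci)):
            raise ValueError("stack, poses and defoci must have equal length")


def make_dataset(
    spec: PhantomSpec,
    n_particles: int,
    defocus_range: tuple[float, float] = DEFAULT_STUDY["defocus_range"],
    noise_sigma: float = 0.0,
    seed: int = 0,
    optics: OpticsParams | None = None,
    orientation: str = "uniform",
    beta_preferred: float = 60.0,
    noise_relative: bool = False,
    noise_only: bool = False,
    mirror: bool = False,
) -> SyntheticDataset:
    """Simulate a full particle stack from a phantom.

    ``noise_relative=True`` interprets ``noise_sigma`` as a multiple of the
    RMS of each noiseless image; ``noise_only=True`` replaces the signal
    with pure noise of that sigma (negative-control datasets);
    ``mirror=True`` images the point inversion of the phantom (the
    opposite-hand molecule) with the same pose/defocus/noise draws.  The
    whole dataset is a deterministic function of (spec, parameters, seed).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    optics = optics or OpticsParams(
        voltage=DEFAULT_STUDY["voltage"],
        pixel_size=spec.pixel_size,
        curvature_scale=DEFAULT_STUDY["curvature_scale"],
    )
    if optics.pixel_size != spec.pixel_size:
        raise ValueError("optics pixel size must match the phantom pixel size")

    truth = build_phantom(spec)
    truth_hand = spec.chirality
    if mirror:
        truth = invert_grid(truth)
        flip = {"right-helix": "left-helix", "left-helix": "right-helix"}
        truth_hand = flip.get(spec.chirality, spec.chirality)
    grid = GridSpec(box=spec.box, pixel_size=spec.pixel_size)
    ftc = ft3_centered(truth)

    poses = random_poses(n_particles, rng, mode=orientation, beta_preferred=beta_preferred)
    defoci = rng.uniform(defocus_range[0], defocus_range[1], n_particles)

    stack = np.empty((n_particles, spec.box, spec.box))
    for i in range(n_particles):
        ft = _project_ft(ftc, poses[i], defoci[i], optics, grid)
        img = np.real(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ft))))
        sigma = noise_sigma
        if noise_relative and noise_sigma > 0:
            sigma = noise_sigma * float(np.sqrt(np.mean(img**2)))
        if noise_only:
            img = np.zeros_like(img)
        if sigma > 0:
            img = img + rng.normal(0.0, sigma, size=img.shape)
        stack[i] = img

    return SyntheticDataset(
        particle_stack=stack,
        poses=poses,
        defoci=defoci,
        optics=optics,
        truth_volume=truth,
        truth_hand=truth_hand,
        noise_sigma=float(noise_sigma),
        seed=seed,
    )
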