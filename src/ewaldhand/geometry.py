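"""Poses, rotations, and the mapping between 3D grid points and the spheres.

Euler convention: intrinsic ZYZ, angles (alpha, beta, gamma) in degrees,
gamma the in-plane rotation.  ``rotation_matrix(pose)`` maps particle-frame
(image-frame) coordinates into reconstruction-frame coordinates:
q_rec = R @ p_particle.  Gathering therefore evaluates the particle frame
of a reconstruction point as p = R.T @ q.

Inversion of the 3D solution is gamma -> gamma + 180 deg, which for the
(real-valued) raw image equals conjugating its Fourier transform.  Applied
to the phase-corrected complex transform the equivalent data-side operation
is C -> conj(C) with the pose unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "EwaldCoordinates",
    "GridSpec",
    "rotation_matrix",
    "invert_pose",
    "ewald_z_offset",
    "map_grid_point_to_image",
    "map_grid_points",
]


@dataclass(frozen=True)
class Pose:
    """ZYZ Euler triplet in degrees, stored normalized to [0, 360)."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", float(self.alpha) % 360.0)
        object.__setattr__(self, "beta", float(self.beta) % 360.0)
        object.__setattr__(self, "gamma", float(self.gamma) % 360.0)


def rotation_matrix(pose: Pose) -> np.ndarray:
    """R = Rz(alpha) @ Ry(beta) @ Rz(gamma); particle frame -> reconstruction frame."""
    return Rotation.from_euler(
        "ZYZ", [pose.alpha, pose.beta, pose.gamma], degrees=True
    ).as_matrix()


def invert_pose(pose: Pose) -> Pose:
    """The pose of the inverted 3D solution: (alpha, beta, gamma + 180)."""
    return Pose(pose.alpha, pose.beta, pose.gamma + 180.0)


def ewald_z_offset(
    kx: float | np.ndarray,
    ky: float | np.ndarray,
    wavelength: float,
    exact: bool = False,
) -> float | np.ndarray:
    """Height of the Ewald sphere above its tangent plane at (kx, ky), A^-1.

    Default is the paraboloidal small-angle form lambda*|k|^2/2; the exact
    sphere 1/lambda - sqrt(1/lambda^2 - |k|^2) sits behind ``exact=True``.
    A zero wavelength (planar approximation) gives zero offset.
    """
    k2 = np.asarray(kx) ** 2 + np.asarray(ky) ** 2
    if wavelength == 0.0:
        return np.zeros_like(k2) if k2.ndim else 0.0
    if np.any(k2 >= 1.0 / wavelength**2):
        raise ValueError("|k| must be below the Ewald sphere diameter 1/lambda")
    if exact:
        out = 1.0 / wavelength - np.sqrt(1.0 / wavelength**2 - k2)
    else:
        out = wavelength * k2 / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EwaldCoordinates:
    """In-plane frequency plus sphere height for one of the two spheres."""

    kx: float
    ky: float
    z_offset: float
    sphere_sign: int  # +1 Ewald sphere, -1 Friedel mate


@dataclass(frozen=True)
class GridSpec:
    """Cubic reconstruction grid: even box, centered origin at index box//2."""

    box: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.box < 8 or self.box % 2:
            raise ValueError("box must be even and >= 8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def dk(self) -> float:
        """Reciprocal-voxel size, A^-1."""
        return 1.0 / (self.box * self.pixel_size)

    @property
    def k_nyquist(self) -> float:
        return 0.5 / self.pixel_size

    def freqs(self) -> np.ndarray:
        """Centered 1D frequency axis in A^-1 (index box//2 is k=0)."""
        return (np.arange(self.box) - self.box // 2) * self.dk


@lru_cache(maxsize=8)
def _grid_freq_table(box: int, dk: float) -> np.ndarray:
    """(box^3, 3) array of centered frequency vectors, C-order flattening."""
    ax = (np.arange(box) - box // 2) * dk
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    # axis order (z, y, x) matches the C-order volume layout; column order
    # below is (x, y, z) so rows are ordinary coordinate vectors.
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def grid_freq_table(grid: GridSpec) -> np.ndarray:
    return _grid_freq_table(grid.box, grid.dk)


def map_grid_points(
    qvecs: np.ndarray, pose: Pose, wavelength: float
) -> dict[str, np.ndarray]:
    """Vectorized gather geometry for reconstruction-frame frequency vectors.

    Parameters
    ----------
    qvecs : (n, 3) frequency vectors in A^-1 (reconstruction frame).
    wavelength : the *curvature* wavelength (may be scaled or zero).

    Returns a dict with particle-frame in-plane coordinates ``kx, ky``,
    height ``zeta``, sphere offset ``z_offset`` and the signed distances
    ``d_ewald = zeta - z_offset``, ``d_mate = zeta + z_offset`` used as
    kernel arguments.
    """
    rot = rotation_matrix(pose)
    p = qvecs @ rot  # rows p = R.T @ q
    kx, ky, zeta = p[:, 0], p[:, 1], p[:, 2]
    zoff = wavelength * (kx**2 + ky**2) / 2.0
    return {
        "kx": kx,
        "ky": ky,
        "zeta": zeta,
        "z_offset": zoff,
        "d_ewald": zeta - zoff,
        "d_mate": zeta + zoff,
    }


def map_grid_point_to_image(
    recon_point: tuple[int, int, int],
    pose: Pose,
    wavelength: float,
    grid_spec: GridSpec,
):
    """Scalar gather geometry for one reconstruction grid index (iz, iy, ix).

    Returns ``(ewald, mate, image_xy, (d_ewald, d_mate))`` where ``ewald``
    and ``mate`` are :class:`EwaldCoordinates`, ``image_xy`` the in-plane
    frequency (A^-1) at which the image transform is sampled, or ``None``
    when the point falls outside the reconstruction band.
    """
    iz, iy, ix = recon_point
    half = grid_spec.box // 2
    q = np.array(
        [
            (ix - half) * grid_spec.dk,
            (iy - half) * grid_spec.dk,
            (iz - half) * grid_spec.dk,
        ]
    )
    if np.linalg.norm(q) > grid_spec.k_nyquist:
        return None
    out = map_grid_points(q[None, :], pose, wavelength)
    kx, ky = float(out["kx"][0]), float(out["ky"][0])
    zoff = float(out["z_offset"][0])
    ewald = EwaldCoordinates(kx, ky, zoff, +1)
    mate = EwaldCoordinates(kx, ky, zoff, -1)
    return ewald, mate, (kx, ky), (float(out["d_ewald"][0]), float(out["d_mate"][0]))
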