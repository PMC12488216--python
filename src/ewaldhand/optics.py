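"""Electron-optical quantities and the Hermite / anti-Hermite factorization.

The weak-phase image model used throughout the package: a particle with
(real) scattering density f has a 3D transform F.  At in-plane spatial
frequency k the detector image transform is

    I(k) = i e^{-i phi(k)} F(p+) - i e^{+i phi(k)} F(p-),

where p+/p- are the points on the Ewald sphere and its Friedel mate at that
in-plane frequency and phi = 2*pi*W is the defocus wavefront phase,
W(k) = -z*lambda*k^2/2 (positive z = underfocus).  Phase correction
multiplies the image transform by e^{+i phi}; the corrected transform is
then split into its Hermite (real-image) and anti-Hermite (imaginary-image)
components, which feed the two separate 3D reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants as _const

__all__ = [
    "OpticsParams",
    "WavefrontField",
    "ComponentImages",
    "electron_wavelength",
    "depth_of_focus",
    "curvature_threshold_resolution",
    "compute_wavefront",
    "phase_correct_image",
    "factorize_components",
    "conjugate_mirror",
]

#: Sign convention shared by the simulator and the corrector: the forward
#: model attenuates the Ewald-sphere term with exp(-i*phi) and the
#: correction multiplies the observed transform by exp(+i*phi).
PHASE_CORRECTION_SIGN = +1


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of beam electrons, in Angstrom.

    lambda = h*c / sqrt(e*V * (2*m0*c^2 + e*V)), V in volts.
    300 kV gives 0.019687 A.
    """
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    ev = _const.e * voltage_kv * 1e3  # beam energy in joules
    rest = _const.m_e * _const.c**2
    lam_m = _const.h * _const.c / np.sqrt(ev * (2.0 * rest + ev))
    return float(lam_m * 1e10)


def depth_of_focus(resolution_d: float, wavelength: float) -> float:
    """Depth of focus L = 2 d^2 / lambda (Angstrom).

    The axial extent over which the planar (flat Ewald sphere)
    approximation holds at resolution d.
    """
    if resolution_d <= 0 or wavelength <= 0:
        raise ValueError("resolution and wavelength must be positive")
    return 2.0 * resolution_d**2 / wavelength


def curvature_threshold_resolution(radius_of_gyration: float, wavelength: float) -> float:
    """Resolution d* = sqrt(2 Rg lambda) where curvature becomes material.

    At d* the wavefront spread across the particle's defocus range
    (+-Rg around its centre) reaches 0.5 waves (Rg*lambda/d*^2 = 1/2), so
    within-particle defocus variation starts to affect the reconstruction.
    """
    if radius_of_gyration <= 0 or wavelength <= 0:
        raise ValueError("radius of gyration and wavelength must be positive")
    return float(np.sqrt(2.0 * radius_of_gyration * wavelength))


@dataclass(frozen=True)
class OpticsParams:
    """Per-particle electron-optical parameters.

    Parameters
    ----------
    voltage : accelerating voltage in kV.
    pixel_size : detector pixel size in Angstrom.
    base_defocus_z : defocus of the particle centre in Angstrom
        (positive = underfocus).
    spherical_aberration : Cs in mm; carried in metadata but not used by
        the defocus-only wavefront model.
    amplitude_contrast : fraction; carried but not modelled (pure phase
        object).
    curvature_scale : multiplies the wavelength *only* where it sets the
        Ewald-sphere geometry (the sphere offset zeta_E = lambda k^2/2 and
        the sphere sampling in the simulator).  The CTF phase always uses
        the physical wavelength.  1.0 is physical; 0.0 reduces the model to
        the planar approximation; large values exaggerate curvature so the
        imaginary-component signal is strong at desk-scale particle counts.
    """

    voltage: float
    pixel_size: float
    base_defocus_z: float = 10000.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.07
    curvature_scale: float = 1.0
    wavelength: float = field(init=False)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.curvature_scale < 0:
            raise ValueError("curvature_scale must be non-negative")
        object.__setattr__(self, "wavelength", electron_wavelength(self.voltage))

    @property
    def curvature_wavelength(self) -> float:
        """Wavelength used for the Ewald-sphere geometry (A)."""
        return self.wavelength * self.curvature_scale

    def with_defocus(self, defocus: float) -> "OpticsParams":
        return replace(self, base_defocus_z=float(defocus))


@dataclass
class WavefrontField:
    """Defocus phase phi = 2*pi*W on the standard (unshifted) 2D FFT grid."""

    phase_grid: np.ndarray  # radians, shape (box, box)
    defocus_used: float  # Angstrom


def _freq_grid_sq(box_size: int, pixel_size: float) -> np.ndarray:
    """|k|^2 in A^-2 on the unshifted FFT layout."""
    f = np.fft.fftfreq(box_size, d=pixel_size)
    return f[:, None] ** 2 + f[None, :] ** 2


def compute_wavefront(
    optics: OpticsParams, defocus: float, box_size: int
) -> WavefrontField:
    """Evaluate phi(k) = 2*pi*(-z*lambda*|k|^2/2) on the image FFT grid.

    ``defocus`` is in Angstrom (positive = underfocus); the physical
    wavelength is used regardless of ``curvature_scale``.
    """
    if box_size < 8 or box_size % 2:
        raise ValueError("box_size must be even and >= 8")
    k2 = _freq_grid_sq(box_size, optics.pixel_size)
    phase = 2.0 * np.pi * (-defocus * optics.wavelength * k2 / 2.0)
    return WavefrontField(phase_grid=phase, defocus_used=float(defocus))


def phase_correct_image(image_ft: np.ndarray, wavefront: WavefrontField) -> np.ndarray:
    """Multiply the image transform by exp(+i*phi): pure phase shift.

    This is phase correction, not Wiener CTF division: amplitudes are
    untouched, so total power is conserved exactly.
    """
    if image_ft.shape != wavefront.phase_grid.shape:
        raise ValueError(
            f"shape mismatch: image {image_ft.shape} vs wavefront "
            f"{wavefront.phase_grid.shape}"
        )
    return image_ft * np.exp(1j * PHASE_CORRECTION_SIGN * wavefront.phase_grid)


def conjugate_mirror(ft: np.ndarray) -> np.ndarray:
    """Return conj(F(-k)) on the unshifted FFT layout (any dimension).

    The Nyquist row/column of an even grid maps to itself, the only
    self-consistent choice.
    """
    rev = ft[(slice(None, None, -1),) * ft.ndim]
    return np.conj(np.roll(rev, shift=(1,) * ft.ndim, axis=tuple(range(ft.ndim))))


@dataclass
class ComponentImages:
    """Hermite / anti-Hermite factorization of a phase-corrected particle FT.

    hermite_ft satisfies H(k) = conj(H(-k)) (a real image in real space);
    antihermite_ft satisfies A(k) = -conj(A(-k)); their sum reproduces the
    corrected transform exactly.
    """

    hermite_ft: np.ndarray
    antihermite_ft: np.ndarray
    box_size: int
    pixel_size: float

    def inverted_solution(self) -> "ComponentImages":
        """The data-side operation that builds the inverted 3D solution.

        Equivalent to resetting the pose gamma -> gamma + 180 deg, which for
        the *raw* (real-valued) image is the same as conjugating its Fourier
        transform.  On the factorized components it reads
        H -> conj(H) = H(-k) and A -> -conj(A) = A(-k): the Hermite part is
        mirrored, the anti-Hermite part mirrored through the same in-plane
        rotation (note -conj, not conj — conjugation alone would undo the
        phase correction's sign rather than rotate the image).
        """
        return ComponentImages(
            hermite_ft=np.conj(self.hermite_ft),
            antihermite_ft=-np.conj(self.antihermite_ft),
            box_size=self.box_size,
            pixel_size=self.pixel_size,
        )


def factorize_components(
    corrected_ft: np.ndarray, pixel_size: float = 1.0
) -> ComponentImages:
    """Split a corrected particle FT into Hermite and anti-Hermite parts.

    H(k) = (F(k) + conj(F(-k)))/2,  A(k) = (F(k) - conj(F(-k)))/2.
    """
    mirror = conjugate_mirror(corrected_ft)
    hermite = 0.5 * (corrected_ft + mirror)
    anti = 0.5 * (corrected_ft - mirror)
    return ComponentImages(
        hermite_ft=hermite,
        antihermite_ft=anti,
        box_size=corrected_ft.shape[0],
        pixel_size=pixel_size,
    )
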