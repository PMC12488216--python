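"""FSC machinery, R^2 modulation, Wiener filtering and the handedness verdict.

The main statistic is the I-R FSC: the shell correlation between the
imaginary-component reconstruction and the R^2-modulated real-component
reconstruction.  Because the inverted solution's maps are the inversion of
MapR and the inversion-with-sign-flip of MapI, the I-R FSC of the inverted
solution is the exact negation of the as-given curve — the two curves are
mirror images by construction.  A positive curve (beyond the null
threshold) says the solution's hand is correct; a negative one says the
inverse is; small scores are indeterminate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .recon import (
    ReconResult,
    ReconstructedVolume,
    finalize_volume,
    ft3_centered,
    ift3_centered,
    shell_index_grid,
)

__all__ = [
    "FSCCurve",
    "HandednessReport",
    "fsc",
    "r2_modulate",
    "wiener_filter",
    "irfsc",
    "predicted_irfsc",
    "handedness_verdict",
    "handedness_report",
    "snr_from_halfmap_fsc",
    "kernel_correlation_volume",
]


@dataclass
class FSCCurve:
    """Per-shell correlation values on a centered cubic Fourier grid."""

    shell_centers: np.ndarray  # A^-1
    values: np.ndarray  # in [-1, 1]
    n_voxels_per_shell: np.ndarray
    zero_power_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_power_flags is None:
            self.zero_power_flags = np.zeros(len(self.values), dtype=bool)

    def resolutions(self) -> np.ndarray:
        """Shell resolution labels in Angstrom (inf at the DC shell)."""
        with np.errstate(divide="ignore"):
            return np.where(self.shell_centers > 0, 1.0 / self.shell_centers, np.inf)

    def negated(self) -> "FSCCurve":
        return FSCCurve(
            shell_centers=self.shell_centers.copy(),
            values=-self.values,
            n_voxels_per_shell=self.n_voxels_per_shell.copy(),
            zero_power_flags=self.zero_power_flags.copy(),
        )


def _as_density(vol) -> np.ndarray:
    return vol.density if isinstance(vol, ReconstructedVolume) else np.asarray(vol)


def fsc(vol_a, vol_b, n_shells: int | None = None, pixel_size: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two real-space maps.

    Shells are spherical annuli one reciprocal voxel wide;
    FSC(s) = Re(sum A conj(B)) / sqrt(sum |A|^2 * sum |B|^2).  Shells where
    either map has zero power are reported as 0 and flagged.
    """
    a = _as_density(vol_a)
    b = _as_density(vol_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    box = a.shape[0]
    n_shells = n_shells or box // 2
    fa = ft3_centered(a)
    fb = ft3_centered(b)
    shells = shell_index_grid(box)
    mask = shells < n_shells
    lab = shells[mask].ravel()

    cross = np.bincount(lab, weights=np.real(fa[mask] * np.conj(fb[mask])).ravel(),
                        minlength=n_shells)
    pa = np.bincount(lab, weights=(np.abs(fa[mask]) ** 2).ravel(), minlength=n_shells)
    pb = np.bincount(lab, weights=(np.abs(fb[mask]) ** 2).ravel(), minlength=n_shells)
    counts = np.bincount(lab, minlength=n_shells)

    zero = (pa <= 0) | (pb <= 0)
    denom = np.sqrt(np.where(zero, 1.0, pa * pb))
    values = np.where(zero, 0.0, cross / denom)
    dk = 1.0 / (box * pixel_size)
    return FSCCurve(
        shell_centers=np.arange(n_shells) * dk,
        values=np.clip(values, -1.0, 1.0),
        n_voxels_per_shell=counts,
        zero_power_flags=zero,
    )


def r2_modulate(vol: ReconstructedVolume) -> np.ndarray:
    """Multiply the real-component map by R^2 (voxel units from the centre).

    The imaginary-component reconstruction is inherently modulated by the
    squared beam-direction offset of the density it uses; applying R^2 to
    the real map makes the two comparable.  R^2 is inversion-invariant so
    the modulation cannot change the sign of the I-R correlation.  Only
    the real map is modulated; an imaginary-component input is rejected.
    """
    if vol.component != "real":
        raise ValueError("R^2 modulation applies to the real-component map only")
    box = vol.density.shape[0]
    ax = np.arange(box) - box // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return vol.density * (xx**2 + yy**2 + zz**2).astype(float)


def wiener_filter(vol: np.ndarray | ReconstructedVolume, per_shell_snr: np.ndarray):
    """Attenuate each resolution shell by SNR/(SNR+1)."""
    density = _as_density(vol)
    snr = np.asarray(per_shell_snr, dtype=float)
    if np.any(snr < 0):
        raise ValueError("per-shell SNR must be non-negative")
    box = density.shape[0]
    shells = shell_index_grid(box)
    gain = np.ones(shells.max() + 1)
    m = min(len(snr), len(gain))
    gain[:m] = snr[:m] / (snr[:m] + 1.0)
    gain[m:] = 0.0
    ft = ft3_centered(density) * gain[shells]
    return np.real(ift3_centered(ft))


def snr_from_halfmap_fsc(halfmap_values: np.ndarray, cap: float = 1e3) -> np.ndarray:
    """Full-map spectral SNR from half-map FSC: 2*FSC/(1-FSC), floored at 0.

    FSC -> 1 is capped at a large finite ceiling.
    """
    f = np.clip(np.asarray(halfmap_values, dtype=float), 0.0, None)
    snr = 2.0 * f / np.maximum(1.0 - f, 1e-12)
    return np.minimum(snr, cap)


def irfsc(
    map_real: ReconstructedVolume,
    map_imag: ReconstructedVolume,
    n_shells: int | None = None,
    pixel_size: float | None = None,
) -> tuple[FSCCurve, FSCCurve]:
    """The I-R FSC pair (as-given, inverted solution).

    as_given = FSC(R^2 * MapR, MapI).  The inverted solution's curve is not
    recomputed: the factorization guarantees it is the exact negation, so
    it is derived bit-for-bit as such.
    """
    if map_real.density.shape != map_imag.density.shape:
        raise ValueError("grid mismatch between real and imaginary maps")
    px = pixel_size if pixel_size is not None else map_real.grid.pixel_size
    as_given = fsc(r2_modulate(map_real), map_imag.density, n_shells, pixel_size=px)
    return as_given, as_given.negated()


def predicted_irfsc(
    halfmap_fsc: FSCCurve,
    weight_ratio_per_shell: np.ndarray,
    compensation: float = 1.0,
) -> FSCCurve:
    """Predicted I-R FSC from the half-map FSC and the kernel weight ratio.

    SNR_R(s) = 2 FSC(s)/(1-FSC(s)); SNR_I(s) = compensation *
    weight_ratio(s) * SNR_R(s) where weight_ratio is the per-shell ratio of
    accumulated imaginary to real kernel weights (sum w^2).  The prediction
    is the correlation of two noisy observations of a common signal:
    sqrt[(SNR_R/(1+SNR_R)) * (SNR_I/(1+SNR_I))].
    """
    snr_r = snr_from_halfmap_fsc(halfmap_fsc.values)
    ratio = np.asarray(weight_ratio_per_shell, dtype=float)
    if len(ratio) < len(snr_r):
        ratio = np.pad(ratio, (0, len(snr_r) - len(ratio)))
    snr_i = compensation * ratio[: len(snr_r)] * snr_r
    pred = np.sqrt((snr_r / (1.0 + snr_r)) * (snr_i / (1.0 + snr_i)))
    return FSCCurve(
        shell_centers=halfmap_fsc.shell_centers.copy(),
        values=pred,
        n_voxels_per_shell=halfmap_fsc.n_voxels_per_shell.copy(),
    )


def kernel_correlation_volume(sigma: float) -> float:
    """Effective voxel correlation volume of the Gaussian deposit kernel.

    Values deposited with a Gaussian kernel of width sigma (voxels) are
    correlated over neighbouring Fourier voxels; the null variance of a
    shell correlation therefore scales with this factor rather than 1.
    For kernel K ~ exp(-d^2/2 sigma^2) the map correlation is
    rho(D) = exp(-D^2/4 sigma^2) per axis and the variance inflation is
    sum_D rho^2 over the 3D integer lags: (sum_m exp(-m^2/2 sigma^2))^3.
    """
    m = np.arange(-20, 21)
    one_d = float(np.sum(np.exp(-(m**2) / (2.0 * sigma**2))))
    return one_d**3


@dataclass
class HandednessReport:
    irfsc_as_given: FSCCurve
    irfsc_inverted: FSCCurve
    predicted_irfsc: FSCCurve | None
    halfmap_fsc_real: FSCCurve | None
    halfmap_fsc_imag: FSCCurve | None
    verdict: str  # 'as_given' | 'inverted' | 'indeterminate'
    verdict_score: float
    null_sigma: float
    threshold_sigmas: float
    validation_flag: str  # 'consistent' | 'inconsistent-with-prediction'

    def to_dict(self) -> dict:
        def curve(c: FSCCurve | None):
            if c is None:
                return None
            return {
                "shell_center_invA": c.shell_centers.tolist(),
                "values": c.values.tolist(),
                "n_voxels": c.n_voxels_per_shell.tolist(),
            }

        return {
            "verdict": self.verdict,
            "verdict_score": self.verdict_score,
            "null_sigma": self.null_sigma,
            "threshold_sigmas": self.threshold_sigmas,
            "validation_flag": self.validation_flag,
            "irfsc_as_given": curve(self.irfsc_as_given),
            "irfsc_inverted": curve(self.irfsc_inverted),
            "predicted_irfsc": curve(self.predicted_irfsc),
            "halfmap_fsc_real": curve(self.halfmap_fsc_real),
            "halfmap_fsc_imag": curve(self.halfmap_fsc_imag),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _curve_score(
    curve: FSCCurve,
    kernel_sigma: float,
    shell_weights: np.ndarray | None = None,
    effective_n: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted Fisher-z score of a curve and its null standard deviation.

    Each shell contributes w_s * n_eff * z with z = atanh(FSC) and
    n_eff = (voxels/2) / kernel correlation volume (half for Friedel
    redundancy, divided by the deposit kernel's correlation volume).
    ``shell_weights`` concentrates the average where signal is possible —
    the caller passes the predicted I-R FSC, so shells whose accumulated
    imaginary weight is zero contribute nothing, which is what makes the
    across-resolution average sensitive.  ``effective_n`` overrides the
    raw half-shell voxel counts with effective independent counts (e.g.
    the participation ratio of the imaginary accumulator's weights, which
    collapses for preferred-orientation coverage).  The DC shell and
    zero-power shells are excluded.  Under the null, z_s ~ N(0, 1/n_eff)
    per shell, so Var(score) = sum (w n_eff)^2 / (n_eff - 3).
    """
    corr = kernel_correlation_volume(kernel_sigma)
    score = 0.0
    var = 0.0
    for s in range(1, len(curve.values)):
        if curve.zero_power_flags[s]:
            continue
        w = 1.0 if shell_weights is None else float(max(shell_weights[s], 0.0))
        if w == 0.0:
            continue
        half_shell = curve.n_voxels_per_shell[s] / 2.0
        if effective_n is not None:
            half_shell = min(half_shell, float(effective_n[s]) / 2.0)
        n_eff = half_shell / corr
        if n_eff < 4.0:
            continue
        z = math.atanh(float(np.clip(curve.values[s], -0.999999, 0.999999)))
        score += w * n_eff * z
        var += (w * n_eff) ** 2 / max(n_eff - 3.0, 1.0)
    return score, math.sqrt(var)


def handedness_verdict(
    irfsc_as_given: FSCCurve,
    predicted: FSCCurve | None = None,
    kernel_sigma: float = 0.75,
    threshold_sigmas: float = 3.0,
    halfmap_fsc_real: FSCCurve | None = None,
    halfmap_fsc_imag: FSCCurve | None = None,
    effective_n: np.ndarray | None = None,
) -> HandednessReport:
    """Summarize the mirror curves into a verdict.

    The score averages Fisher-transformed correlations across resolutions:
    each shell is weighted by its independent voxel count times the
    predicted I-R FSC when a prediction is available, so shells that carry
    no imaginary-component weight contribute neither signal nor variance.
    Because map statistics of the real component are inversion-invariant,
    the prediction — hence the weighting — is identical for both hands,
    and the inverted solution's score is the exact negation.  |score|
    above ``threshold_sigmas`` null sigmas decides the hand by sign;
    below, the verdict is indeterminate.  When a prediction is supplied
    and is itself significant while the observation is not — the observed
    curve varies in sign at noise level although signal was expected —
    the report is flagged inconsistent-with-prediction.
    """
    weights = None if predicted is None else predicted.values
    score, sigma = _curve_score(irfsc_as_given, kernel_sigma, weights, effective_n)
    if sigma > 0 and score > threshold_sigmas * sigma:
        verdict = "as_given"
    elif sigma > 0 and score < -threshold_sigmas * sigma:
        verdict = "inverted"
    else:
        verdict = "indeterminate"

    flag = "consistent"
    if predicted is not None and verdict == "indeterminate":
        pred_score, pred_sigma = _curve_score(predicted, kernel_sigma, weights, effective_n)
        if pred_sigma > 0 and pred_score > threshold_sigmas * pred_sigma:
            flag = "inconsistent-with-prediction"

    return HandednessReport(
        irfsc_as_given=irfsc_as_given,
        irfsc_inverted=irfsc_as_given.negated(),
        predicted_irfsc=predicted,
        halfmap_fsc_real=halfmap_fsc_real,
        halfmap_fsc_imag=halfmap_fsc_imag,
        verdict=verdict,
        verdict_score=score,
        null_sigma=sigma,
        threshold_sigmas=threshold_sigmas,
        validation_flag=flag,
    )


def handedness_report(
    result: ReconResult,
    compensation: float = 1.0,
    threshold_sigmas: float = 3.0,
    weight_floor: float = 1e-3,
) -> HandednessReport:
    """Full analysis of one dataset reconstruction.

    Finalizes full and half maps for both components, estimates per-shell
    SNR from the half-map FSCs, Wiener-filters the full maps, computes the
    I-R FSC pair, the predicted curve from the accumulated kernel weights,
    and the verdict.
    """
    px = result.grid.pixel_size
    acc_r = result.acc_real
    acc_i = result.acc_imag
    map_r = finalize_volume(acc_r, weight_floor)
    map_i = finalize_volume(acc_i, weight_floor)

    half_maps_r = [finalize_volume(h, weight_floor) for h in result.half_real]
    half_maps_i = [finalize_volume(h, weight_floor) for h in result.half_imag]
    hm_fsc_r = fsc(half_maps_r[0], half_maps_r[1], pixel_size=px)
    hm_fsc_i = fsc(half_maps_i[0], half_maps_i[1], pixel_size=px)

    snr_r = snr_from_halfmap_fsc(hm_fsc_r.values)
    snr_i = snr_from_halfmap_fsc(hm_fsc_i.values)
    map_r.per_shell_snr = snr_r
    map_i.per_shell_snr = snr_i

    filt_r = ReconstructedVolume(
        density=wiener_filter(map_r, snr_r),
        component="real", hand="as_given", grid=result.grid, per_shell_snr=snr_r,
    )
    filt_i = ReconstructedVolume(
        density=wiener_filter(map_i, snr_i),
        component="imaginary", hand="as_given", grid=result.grid, per_shell_snr=snr_i,
    )

    curve_given, _curve_inv = irfsc(filt_r, filt_i)

    w_r = acc_r.shell_weight_sums()
    w_i = acc_i.shell_weight_sums()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w_r > 0, w_i / np.maximum(w_r, 1e-300), 0.0)
    predicted = predicted_irfsc(hm_fsc_r, ratio, compensation)

    return handedness_verdict(
        curve_given,
        predicted=predicted,
        kernel_sigma=result.kernel.sigma,
        threshold_sigmas=threshold_sigmas,
        halfmap_fsc_real=hm_fsc_r,
        halfmap_fsc_imag=hm_fsc_i,
        effective_n=acc_i.shell_participation(),
    )
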