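# Methods

## Image model

The forward model is the weak-phase object approximation with explicit
Ewald-sphere geometry. A particle with real scattering density f (3D
transform F, Hermitian) at pose R and defocus z (positive = underfocus,
measured to the particle centre) produces the image transform

    I(k) = i e^{−iφ(k)} F(R p₊) − i e^{+iφ(k)} F(R p₋)

with p± = (kx, ky, ±ζ_E), ζ_E = λ_c|k|²/2, and φ = 2πW, W = −zλ|k|²/2.
The quadratic |F_e|² intensity term is dropped, keeping the model linear
so reconstructions have an exact ground truth; in the planar limit
(ζ_E = 0) the model reduces to the standard CTF image I = 2 sin φ · F.
Amplitude contrast, spherical aberration, astigmatism and detector MTF
are not modelled (they are carried in metadata only); a pure phase object
consequently has zero contrast exactly in focus.

Two distinct roles of the wavelength are separated deliberately:
the CTF phase φ always uses the physical λ of the beam, while the sphere
geometry uses λ_c = λ × `curvature_scale`. `curvature_scale = 1` is
physical; `0` is the planar approximation with the CTF retained (the
regression limit in the tests); large values exaggerate the sphere
separation so that desk-scale datasets (hundreds of particles) carry the
curvature signal that real data shows only at 10⁵–10⁶ particles. The
estimator algebra below is independent of the link between φ and ζ_E, so
this decoupling changes statistics, not correctness.

## Factorization and the matched gather weights

Phase correction multiplies the image transform by e^{+iφ}. Splitting
the corrected transform C into its Hermite and anti-Hermite parts,
H(k) = (C(k)+C̄(−k))/2 and A(k) = (C(k)−C̄(−k))/2, the exact coefficients
are

    H = a F₊ + a* F₋,   a = i cos φ e^{−iφ} = ½ sin 2φ + i (1+cos 2φ)/2
    A = b F₊ − b* F₋,   b = − sin φ e^{−iφ} = −½ sin 2φ + i (1−cos 2φ)/2

(F± the two sphere samples). Writing S = F₊+F₋ and D = F₊−F₋:
H = Re(a)·S + i Im(a)·D and A = Re(b)·D + i Im(b)·S. The
structure-carrying channels are therefore Re(a) = +½ sin 2φ for the real
component (sum channel) and Re(b) = −½ sin 2φ for the imaginary
component (difference channel): both interference amplitudes are the
planar CTF of the corrected image, up to sign. The gather weights are

    w_R = sin(2φ) · [K(d₊) + K(d₋)]           (real map)
    w_I = −sin(2φ) · [K(d₊) − K(d₋)]          (imaginary map)

with K a Gaussian kernel (σ = 0.75 reciprocal voxels, truncated at 3σ)
in the distance to each sphere, evaluated in reciprocal voxels. Per
component two sums accumulate: Σ w·value and Σ w². The orthogonal
channels (i Im(a)·D in H, i Im(b)·S in A) have purely imaginary mean
coefficients over the defocus ensemble; both accumulated grids are
Hermitian by construction, so taking the real part of the inverse
transform removes those cross-channel terms to first order. This is why
the real-signal leakage into the imaginary map — which a mismatched
weight such as 1−cos 2φ would convert into a large hand-independent
I-R correlation — is structurally suppressed.

A residual, fluctuation-level cross-talk survives at very low resolution
where φ does not wrap across the defocus spread; it decays with particle
count and with defocus diversity, which is why the default defocus range
is wide (5 000–25 000 Å).

## Reconstruction mechanics

The gather traverses the full reconstruction grid per particle
(vectorized; only the slab |d±| ≤ kernel support contributes), samples
the centered 2D component transforms by bilinear interpolation at the
rotated in-plane coordinate, and deposits weight·value and weight².
Euler convention is intrinsic ZYZ, (α, β, γ) in degrees, γ in-plane;
`rotation_matrix` maps particle-frame to reconstruction-frame vectors.
Frequencies are in Å⁻¹ on centered grids (origin at index box/2); the
Nyquist row/column maps to itself under −k (the only consistent choice on
even grids). The band is limited to (box/2 − 2) voxels so bilinear
stencils stay in range.

`finalize_volume` divides Σ w·value by Σ w² with a per-shell relative
floor (10⁻³ of the shell median of positive weights); voxels below the
floor are zeroed. The division is a Wiener-style regularized estimator;
per-shell scale factors cancel in every correlation downstream. The
imaginary map is extracted with a global sign constant
(`HANDEDNESS_SIGN`), the detector-handedness calibration the method
requires, fixed once so that a self-consistent dataset (true poses, true
defoci) yields a positive I-R FSC.

Solution inversion is γ → γ+180°, or equivalently, on the data side,
H → conj(H), A → −conj(A) with poses unchanged
(`ComponentImages.inverted_solution`). Under it the real map inverts
through the origin and the imaginary map inverts and flips sign — the
identity is exact on the accumulators (verified to 10⁻¹⁰ in the tests),
so the inverted solution's maps and curves are derived from the original
reconstruction at no extra cost, and the two I-R FSC curves are exact
mirror images bit for bit.

Note an identity of the forward model worth stating explicitly: a
point-inverted phantom imaged with self-consistent pose labels is a
correctly solved structure of the mirror molecule, and its I-R FSC is
positive again. What the verdict detects is a mismatch between the data's
hand and the solution's hand — pose labels produced by refining against a
wrong-hand reference (equivalently, γ+180° labels). The "flip" experiment
in the acceptance tests is constructed accordingly.

## I-R FSC, prediction and verdict

The imaginary reconstruction is intrinsically weighted by the squared
beam-direction offset of the density it uses, so before correlating,
the real map is multiplied by R² (squared voxel distance from the map
centre; inversion-invariant, hence sign-safe). Both maps are
Wiener-filtered per shell with SNR = 2·FSC/(1−FSC) from the even/odd
half-map FSC of their own component (half-sets split by particle index,
deterministic). The I-R FSC is then the standard shell correlation
Re Σ A·B̄ / √(Σ|A|²·Σ|B|²) in one-voxel annuli (ties rounded half-up).

The predicted I-R FSC converts the real component's half-map FSC into a
full-map SNR, scales it by the per-shell ratio Σw²_imag/Σw²_real of
accumulated kernel weights (times a compensation factor, default 1.0,
which absorbs the narrower-than-physical kernel and shape assumptions),
and combines the two SNRs as the correlation of two noisy observations of
a common signal: √[(SNR_R/(1+SNR_R))·(SNR_I/(1+SNR_I))].

The verdict averages Fisher-transformed correlations across resolutions:
score = Σ_s w_s·n_s·atanh(FSC_s), with w_s the predicted I-R FSC (shells
that cannot carry imaginary signal contribute neither signal nor
variance) and n_s an effective independent-voxel count: half the shell's
voxels (Friedel redundancy), divided by the kernel correlation volume
(Σ_m e^{−m²/2σ²})³ ≈ 6.6 for σ = 0.75 (deposited values are smoothed
over neighbouring voxels), and capped by the participation ratio
(Σw)²/Σw² of the imaginary accumulator's weights within the shell. The
participation ratio is what keeps the null honest under anisotropic
coverage: preferred-orientation data concentrate the imaginary weight on
a thin annulus of each shell, and treating all shell voxels as
independent would overstate significance several-fold. Under the null
the score variance is Σ (w_s n_s)²/(n_s−3); the verdict is the score's
sign when |score| exceeds 3σ, else `indeterminate`. When the predicted
curve is itself significant while the observation is not, the report is
flagged `inconsistent-with-prediction` — the negative-control behaviour
of a dataset whose half-map FSC looks fine but whose reconstruction is
wrong.

## Synthetic data and study conditions

The generator builds sum-of-Gaussian phantoms; chirality comes from blob
centres on a helical path with signed pitch (geometry scales with the
box: radius 5/16 of the extent, height 5/8, blob σ 1/24 — 45/90/6 Å at
the default box). The default study conditions are a 48³ box at
3 Å/pixel, 300 kV, curvature ×100, 600 particles, defoci uniform in
5 000–25 000 Å, and white Gaussian real-space noise with σ = 0.5× each
image's signal RMS. Under these conditions the particle diameter
(~110 Å) exceeds the depth of focus at Nyquist (2d²/λ_c ≈ 37 Å), the
regime where curvature is informative. Pose modes: uniform over SO(3)
(cos β uniform) and preferred orientation (fixed viewing direction,
random in-plane γ) for the null tests; `noise_only` datasets keep the
noise amplitude of the signal case but no signal.

What the simulations do not emulate: structural heterogeneity, amplitude
contrast, aberrations beyond defocus, detector MTF, dose and motion
effects, and pose/defocus estimation error. Passing tests therefore show
the factorization, weighting and statistics are internally correct and
self-consistent under the stated model — not that every real dataset
carries a usable signal (real data need ~10⁵ particles at physical λ,
and disorder correlated with radius attenuates the correlation).

## Numerical choices and limitations

- Bilinear (2D) and trilinear (3D) interpolation; the brute-force oracle
  tests pin their behaviour exactly.
- All FFTs through numpy with centered-layout wrappers; accumulation
  order is fixed, so results are bit-reproducible and independent of any
  thread setting.
- Shells: one reciprocal voxel wide, |k| rounded half-up; DC shell
  excluded from scores.
- Wiener SNR is clipped to [0, 10³]; half-map FSC below 0 counts as 0.
- The paraboloidal sphere (ζ_E = λk²/2) is the default; the exact sphere
  is available in `ewald_z_offset(..., exact=True)` and differs by less
  than 10⁻⁴ relative at the resolutions involved.
- Box sizes ≲ 32 leave few signal shells and a slim 3σ margin even for
  noiseless data; the study box of 48 is the practical minimum at which
  the verdict has a comfortable margin.
- The significance model treats shells as independent after the
  kernel-volume and participation corrections; the R² modulation mixes
  neighbouring shells slightly, which the Monte-Carlo null tests show is
  negligible at the 3σ threshold.
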