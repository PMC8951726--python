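# Methods

## Decay model and simulation

A pixel's photon arrival time within one excitation period `T = 1/f_rep`
(12.5 ns at the default 80 MHz) is modelled as

    t = (t_irf + t_decay) mod T

where `t_irf ~ Normal(irf_center, irf_sigma)` is the instrument response
(IRF) and `t_decay` is drawn from the emitter's decay — a mixture of
exponentials `Σᵢ αᵢ · Exp(τᵢ)` with photon fractions `αᵢ` summing to 1. The
modulo fold is the incomplete-decay model for repetitive excitation: photons
emitted after the next pulse are recorded relative to that pulse. Folding is
what keeps single-exponential emitters exactly on the universal semicircle at
any lifetime, because the Fourier coefficient of the wrapped density at any
harmonic of `1/T` equals that of the unwrapped exponential:
`∫₀ᵀ f_wrap(t)·e^{inωt} dt / ∫₀ᵀ f_wrap = 1/(1 − inωτ)`.

Time bins partition `[0, T)` half-open, left-edge indexed; a bin's value is
the integral of the arrival-time density over the bin. The IRF⊗exponential
density is the ex-Gaussian; bin integrals are computed as CDF differences
(`scipy.stats.exponnorm`) summed over every period shift holding
non-negligible mass (the window covers ±10 IRF sigmas and 46 lifetimes, so
the truncated mass is below 1e-15; the profile is renormalised to sum to 1
exactly). IRF widths below 1e-9 ns are treated as a delta (a shifted
exponential CDF) to avoid overflow in the ex-Gaussian shape parameter.

Counts are Poisson: `countsₖ ~ Poisson(brightness · profileₖ + background/K)`
with a single `numpy.random.default_rng(seed)` draw over the whole cube, so a
fixed spec + seed reproduces the cube bit-exactly.

Default acquisition parameters: repetition rate 8e7 Hz, 256 bins,
`irf_sigma` 0.1 ns and `irf_center` 0.5 ns (a realistic confocal TCSPC
response; the calibration step removes its effect, so its exact values are
not load-bearing), background 0. Scenes place disk- or blob-shaped particles
of tens of µm (defaults: 2 µm pixels, ~28 µm particles in a 64×64 field,
standing in for ~100 µm granules imaged at moderate magnification) on a dark
background; blob outlines perturb the disk radius with three low-order
angular harmonics drawn from the scene seed.

Reference lifetimes used throughout: unstained ABS 2.0, PET 2.2, PVC 1.6,
PLA 1.1 ns; stained ABS 2.2, PET 3.2, PVC 3.8, PLA 3.3 ns; Nile red (the
calibration reference) 3.1 ns, single-exponential. A helper builds
two-component species (a 3.1 ns dye-like component plus a polymer component)
with the fraction solved so the intensity-weighted mean lifetime hits a
target; this is only feasible when the target lies between the two component
lifetimes, so stained species whose reported fast lifetime exceeds 3.1 ns
(stained PET/PVC/PLA) are represented by single-exponential stand-ins at the
reported value when a concrete decay is needed — the true component structure
is not identifiable from a fast lifetime alone.

## Discrete phasor transform and the bin-integration correction

The transform is `G + iS = Σₖ Iₖ e^{2πink/K} / Σₖ Iₖ`. For a bin-integrated
wrapped exponential this discrete phasor evaluates in closed form to

    z_disc = e^{-iθ/2} · sinh(a/2) / sinh((a − iθ)/2),   θ = 2πn/K, a = Δ/τ,

which lies on a circle through (0, 0) and (1/cos(θ/2), 0) — slightly larger
than the universal circle. Multiplying by

    c = e^{iθ/2} · cos(θ/2) = (1 + e^{iθ}) / 2

maps that locus exactly onto the universal circle for *every* lifetime
(algebraically: `Re(1/(z_disc·c)) = 1`, the circle condition). The factor is
equivalent to averaging the two bin-edge evaluations of the Fourier sum — a
trapezoidal end correction. This correction is enabled by default and is what
makes the closed-form phasor usable as a strict (1e-9) oracle for the
on-circle property of noise-free profiles.

The residual discretisation error is purely tangential: the corrected phasor
sits at arc position `nωτ' = coth(a/2)·tan(θ/2)` instead of `nωτ`. No
τ-independent linear correction can remove this (the two curves are the same
circle with slightly different parametrisations), and a nonlinear per-pixel
correction would destroy the exact photon-weighted mixing rule, which we
consider the more important invariant. At K = 256 and harmonic 2 the
resulting lifetime bias is below 0.05% for lifetimes ≥ 1 ns (≈1.7% at
0.1 ns), far inside the 2% recovery tolerance used in validation.

Because the correction is a single complex factor, the transform is linear in
the histogram, so the phasor of a summed decay equals the photon-weighted
average of the component phasors to machine precision — the two-species chord
rule holds exactly.

Aliasing guard: harmonics with `n ≥ K/2` are rejected. Zero-photon pixels are
masked invalid (G = S = 0, never NaN-propagated).

## Calibration

A real (or simulated) instrument delays and demodulates every phasor via its
IRF. Calibration measures the intensity-weighted mean phasor of a reference
fluorophore of known single-exponential lifetime (Nile red, 3.1 ns) acquired
under identical conditions and applies the complex factor
`theoretical / measured` — a rotation (phase offset) plus scaling (modulation
factor) — to every pixel. Because period wrapping makes the IRF convolution
circular, an identically-simulated reference removes the IRF effect
essentially exactly; the small remaining systematic is the discretisation
remap noted above (~1e-4 in phasor units), which is why fingerprint centroid
validation allows a 5e-3 slack on circle containment rather than 1e-6.
Calibrating twice is an error; an identity reference is a no-op.

## Filtering

Following the optimized protocol, pixels with fewer than 100 photons are
masked (threshold), then G and S are median-filtered with a 5×5 window.
Order matters and threshold runs first so unreliable pixels never enter the
smoothing windows. The median is computed over the *valid* samples of each
window (masked pixels excluded, never zero-filled), with reflective borders
and the lower median as a deterministic tie-break for even sample counts. The
window edge (5) is interpreted as the vendor's "median filter 5"; the number
of passes is configurable (default 1). The filtered value never leaves the
range of its window's valid samples, and on homogeneous regions the variance
of G is non-increasing — both properties are tested.

## Fingerprints and matching

A fingerprint is the intensity-weighted centroid of a pure species' valid
(G, S) pixels, a cluster radius, and the phase lifetime τ_φ = S/(nωG) of the
centroid (the "fast lifetime"; for the single-exponential fingerprints used
here phase and modulation lifetimes coincide, and phase is the common
real-time display). Default harmonic is 2, which spreads the 1–4 ns clusters
over a wider arc than harmonic 1.

The radius is `k ×` the pooled intensity-weighted per-axis standard deviation
of the cluster, floored at 1e-4 for degenerate clusters. The published
workflow circles clusters by hand; a reproducible artifact needs a
statistical rule, and the coverage of a k·σ circle for an isotropic 2-D
Gaussian cluster is `1 − exp(−k²/2)`: 86.5% at k = 2, 99.8% at k = 3.5. We
default to **k = 3.5** so that a pure species captures (almost) all of its
own pixels while the radius stays an order of magnitude below the distance
between the closest fingerprints at 10⁴ photons/pixel. At 10³ photons/pixel
all pairs of unstained fingerprints remain separated (centroid distance >
sum of radii) except ABS/PET (2.0 vs 2.2 ns), which separate at 10⁴ —
the photon-budget dependence expected for that closest pair.

Matching assigns a query point to the species with the nearest centroid in
Euclidean (G, S) distance, provided the distance does not exceed that
fingerprint's radius; an exact distance tie is reported as unassigned rather
than broken arbitrarily. Libraries store their acquisition context
(repetition rate, harmonic) and refuse cross-context queries, since phasor
position depends on nω.

Classification applies the same rule per pixel (vectorised), then removes
8-connected components smaller than 5 pixels (configurable) as shot-noise
speckle. Classification is per-pixel by default; particles are 8-connected
components of one species (crushed granules are not axis-aligned). Pixel
colors default to red (ABS), green (PET), blue (PVC), pink (PLA); an
alternative mixture palette with yellow PVC is provided, as both appear in
published renderings and neither is canonical.

Model fit uncertainties: centroid standard errors use the intensity-weighted
effective sample size `n_eff = (Σw)²/Σw²`; the fast-lifetime SE is
first-order propagation through τ_φ = S/(nωG) (covariance neglected — the
G–S covariance of on-circle clusters is small relative to the variances, and
the SEs are diagnostic, not inferential).

## Semicircle orientation

We implement the standard convention: τ = 0 at (1, 0), lifetime increasing
monotonically along the arc toward the origin, with the apex (0.5, 0.5) at
nωτ = 1 (≈1.99 ns at 80 MHz, harmonic 1). A statement occasionally seen that
long lifetimes lie "near (0, 1)" is inconsistent with the radius-0.5
semicircle centred at (0.5, 0) and is not reproduced.

## What the synthetic data does and does not emulate

Emulated: 80 MHz pulsed excitation; multi-exponential emitters; Gaussian
IRF with period wrapping; Poisson photon noise; per-pixel photon budgets
(10²–10⁴ used in tests, standing in for frame accumulation); granular
particles on a dark background; out-of-library interferent species with
distinct lifetimes.

Not emulated: optical point-spread blur (particle edges are sharp, so there
are no partial-volume mixed pixels at particle boundaries); detector
afterpulsing and dead time; wavelength-resolved (spectral) signal; spatially
varying background; dye–polymer photophysics of stained particles beyond a
two-component mixture. Consequently, passing tests demonstrate the
correctness of the transform, calibration, filtering and matching machinery
and the statistical behaviour under shot noise — not robustness to optical
blur or detector artifacts in real acquisitions.

## Problem sizes and numerical tolerances

Validation uses 64×64×256-bin cubes (the full-frame 512×512 default exists
but is unnecessary for statistical conclusions), 10⁴ photons/pixel for
lifetime-recovery checks (2% tolerance) and 10²–10⁴ for classification
sweeps. Exact-arithmetic checks (transform vs. brute-force summation, mixing
linearity, library round-trips) use 1e-12 or bit equality; geometry checks
(on-circle) use 1e-9; stochastic checks state their sample sizes and use
SE-based or fixed-percentage bounds. Degenerate inputs are defined, not
accidental: empty scenes give all-zero label maps, zero-photon pixels are
masked, zero-scatter clusters get the floor radius, and an empty particle
table is a valid result.
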