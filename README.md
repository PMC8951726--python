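# phasorprint

FLIM-phasor fingerprinting of microplastics: simulate TCSPC fluorescence-decay
image cubes, transform them to phasor space, build a library of lifetime
"fingerprints" for known polymer species, and classify the pixels of mixed
scenes by nearest-fingerprint matching with pseudo-color rendering and
per-particle statistics.

## The problem

Common microplastics (ABS, PET, PVC, PLA) autofluoresce with distinct
fluorescence lifetimes (τ ≈ 2.0, 2.2, 1.6 and 1.1 ns respectively under
pulsed excitation at 80 MHz). Fluorescence lifetime imaging microscopy (FLIM)
with time-correlated single photon counting (TCSPC) records, per pixel, a
histogram of photon arrival times over one excitation period. Phasor analysis
turns each histogram into a single point without any curve fitting:

    G = Σₖ Iₖ cos(2πnk/K) / Σₖ Iₖ ,   S = Σₖ Iₖ sin(2πnk/K) / Σₖ Iₖ

over K time bins at harmonic n of the repetition frequency. Every
single-exponential decay lands on the *universal semicircle* of radius 0.5
centred at (0.5, 0) — short lifetimes near (1, 0), long lifetimes toward the
origin — and a mixture of two species falls on the chord between their
phasors, weighted by photon contribution. The phase lifetime
τ_φ = S/(nωG) of a cluster centroid is its "fast lifetime".

A pure species forms a tight phasor cluster; its centroid, radius and fast
lifetime constitute a *fingerprint*. A library of fingerprints then lets you
identify each pixel of a mixed sample by proximity in phasor space — and
pixels of substances absent from the library (sediment, SiO₂, chitin, …)
simply stay unassigned instead of being misattributed.

The package is aimed at anyone prototyping or validating lifetime-based
particle identification: the simulator provides decay cubes with exact ground
truth (multi-exponential emitters, Gaussian instrument response, period
wrapping, Poisson photon noise), so every stage of the analysis is testable
without a microscope.

## Worked example

```python
import phasorprint as pp

acq = pp.AcquisitionSpec(seed=5)          # 80 MHz, 256 bins, Gaussian IRF
cubes = {
    name: pp.simulate_uniform_cube(
        pp.SpeciesSpec(name=name, components=[(tau, 1.0)], brightness=1e4),
        acq.model_copy(update={"seed": 5 + i}), shape=(64, 64))
    for i, (name, tau) in enumerate(pp.UNSTAINED_LIFETIMES_NS.items())
}
ref_cube = pp.simulate_uniform_cube(       # Nile red reference, tau = 3.1 ns
    pp.SpeciesSpec(name="ref", components=[(3.1, 1.0)], brightness=1e4),
    acq.model_copy(update={"seed": 99}), shape=(64, 64))
reference = pp.CalibrationRef.from_image(
    pp.phasor_transform(ref_cube, harmonic=2), 3.1)

model = pp.PhasorFingerprintModel.from_cubes(
    cubes, harmonic=2, reference=reference, colors=pp.DEFAULT_COLORS)
results = model.fit()
print(results.summary())
```

prints (seed-dependent in the last digits):

```
Phasor fingerprint library fit
  repetition rate: 80.0 MHz, harmonic: 2
  species: 4, radius rule: 3.50 x pooled SD
         tau_fast_ns  se_tau_ns      G      S   se_G   se_S  radius  n_pixels
species
ABS           2.0019     0.0003 0.1982 0.3989 0.0000 0.0000  0.0057      4096
PET           2.2020     0.0004 0.1697 0.3756 0.0000 0.0000  0.0057      4096
PVC           1.6035     0.0002 0.2784 0.4488 0.0000 0.0000  0.0051      4096
PLA           1.1013     0.0001 0.4498 0.4980 0.0000 0.0000  0.0049      4096
```

Each row is one fingerprint: the recovered fast lifetime (within a few ps of
the 2.0/2.2/1.6/1.1 ns ground truth) with its standard error, the phasor
centroid (G, S) at harmonic 2, and the cluster radius used for matching.
`results.classify(phasor_image)` then labels a mixed scene,
`pp.particle_stats(label_map)` tabulates particle sizes, and
`pp.render_pseudocolor(label_map)` produces the colored identification image.

The same workflow is available from the shell:

```bash
phasorprint demo --out demo_run --seed 1
```

simulates the four pure species plus a 4.5 ns "sediment" interferent, builds
the library, classifies the mixed scene (interferent pixels stay unassigned)
and writes cubes (HDF5), phasor images (TIFF + JSON sidecar), the library
(JSON), a label map, a PNG render, a particle CSV and a hashed run manifest.
Stage-wise subcommands (`simulate`, `phasor`, `calibrate`, `filter`,
`fingerprint build/merge`, `classify`) operate on files for custom workflows.

## Documentation

See `docs/methods.md` for the underlying model: the wrapped ex-Gaussian decay
simulation, the exact bin-integration correction of the discrete phasor
transform, the calibration and filtering conventions, the fingerprint radius
rule, and known limitations of the synthetic data.
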