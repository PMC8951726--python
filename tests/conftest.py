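"""Shared fixtures: acquisition specs and the pure-species pipeline helper."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import phasorprint as pp


@pytest.fixture
def acq():
    """Default 80 MHz / 256-bin acquisition with a small Gaussian IRF."""
    return pp.AcquisitionSpec(seed=0)


@pytest.fixture
def ideal_acq():
    """IRF-free acquisition starting at t = 0 (noise-free oracles)."""
    return pp.AcquisitionSpec(irf_sigma=0.0, irf_center=0.0, seed=0)


def noise_free_cube(components, acq_spec, scale=1.0):
    """Single-pixel cube holding the exact expected decay profile."""
    prof = pp.decay_profile(components, acq_spec) * scale
    return pp.DecayCube(
        counts=prof[None, None, :],
        repetition_rate=acq_spec.repetition_rate,
        bin_width=acq_spec.bin_width_ns,
    )


def run_pure_pipeline(
    tau,
    photons=1e4,
    seed=0,
    shape=(64, 64),
    harmonic=2,
    irf_sigma=0.1,
    irf_center=0.5,
    min_photons=100,
    median_size=5,
    radius_k=3.5,
):
    """Simulate → transform → calibrate → threshold → median → fingerprint.

    The calibration reference is a Nile-red-like 3.1 ns single exponential
    simulated under the identical acquisition (independent seed).  Returns
    (filtered image, fingerprint).
    """
    acq_spec = pp.AcquisitionSpec(
        irf_sigma=irf_sigma, irf_center=irf_center, seed=seed
    )
    species = pp.SpeciesSpec(
        name=f"tau{tau}", components=[(float(tau), 1.0)], brightness=photons
    )
    cube = pp.simulate_uniform_cube(species, acq_spec, shape=shape)

    ref_acq = acq_spec.model_copy(update={"seed": seed + 10_000})
    ref_species = pp.SpeciesSpec(
        name="reference", components=[(pp.NILE_RED_LIFETIME_NS, 1.0)], brightness=1e4
    )
    ref_cube = pp.simulate_uniform_cube(ref_species, ref_acq, shape=shape)
    ref_img = pp.phasor_transform(ref_cube, harmonic=harmonic)
    ref = pp.CalibrationRef.from_image(ref_img, pp.NILE_RED_LIFETIME_NS)

    img = pp.phasor_transform(cube, harmonic=harmonic)
    img = pp.calibrate(img, ref)
    img = pp.threshold_filter(img, min_photons)
    img = pp.median_filter_phasor(img, median_size)
    fp = pp.build_fingerprint(img, species.name, radius_k=radius_k)
    return img, fp


@pytest.fixture
def pure_pipeline():
    return run_pure_pipeline


def run_mixture_scene(
    photons=1e4,
    seed=0,
    shape=(64, 64),
    interferent_tau=None,
    min_particle_size=5,
    diameter_um=28.0,
    harmonic=2,
):
    """Library from pure cubes + classified mixed scene with ground truth.

    Returns (label_map, ground_truth, results).  The library holds the four
    unstained microplastics; an optional interferent species appears in the
    scene but not in the library.
    """
    acq = pp.AcquisitionSpec(seed=seed)
    lib_species = [
        pp.SpeciesSpec(
            name=name,
            components=[(tau, 1.0)],
            brightness=photons,
            color=pp.DEFAULT_COLORS[name],
        )
        for name, tau in pp.UNSTAINED_LIFETIMES_NS.items()
    ]

    ref_species = pp.SpeciesSpec(
        name="reference", components=[(pp.NILE_RED_LIFETIME_NS, 1.0)], brightness=1e4
    )
    ref_cube = pp.simulate_uniform_cube(
        ref_species, acq.model_copy(update={"seed": seed + 90_000}), shape=(48, 48)
    )
    reference = pp.CalibrationRef.from_image(
        pp.phasor_transform(ref_cube, harmonic=harmonic), pp.NILE_RED_LIFETIME_NS
    )

    cubes = {
        sp.name: pp.simulate_uniform_cube(
            sp, acq.model_copy(update={"seed": seed + 1000 + i}), shape=(48, 48)
        )
        for i, sp in enumerate(lib_species)
    }
    model = pp.PhasorFingerprintModel.from_cubes(
        cubes,
        harmonic=harmonic,
        reference=reference,
        colors=pp.DEFAULT_COLORS,
    )
    results = model.fit()

    all_species = list(lib_species)
    interferents = []
    if interferent_tau is not None:
        all_species.append(
            pp.SpeciesSpec(
                name="interferent",
                components=[(float(interferent_tau), 1.0)],
                brightness=photons,
                color="gray",
            )
        )
        interferents = ["interferent"]
    scene = pp.demo_scene(
        shape=shape,
        include=tuple(pp.UNSTAINED_LIFETIMES_NS),
        interferents=tuple(interferents),
        diameter_um=diameter_um,
    )
    mix_cube = pp.simulate_cube(
        scene, all_species, acq.model_copy(update={"seed": seed + 77_000})
    )
    img = pp.phasor_transform(mix_cube, harmonic=harmonic)
    img = pp.calibrate(img, reference)
    img = pp.apply_filters(img, pp.FilterParams())
    label_map = results.classify(
        img, pixel_size=scene.pixel_size, min_particle_size=min_particle_size
    )
    return label_map, mix_cube.ground_truth, results


def per_pixel_accuracy(label_map, ground_truth, species_subset):
    """Fraction of ground-truth particle pixels assigned their true species."""
    pred_species = np.full(label_map.labels.shape, "", dtype=object)
    for lab, (name, _c) in label_map.legend.items():
        pred_species[label_map.labels == lab] = name
    correct = total = 0
    for lab, (name, _c) in ground_truth.legend.items():
        if name not in species_subset:
            continue
        sel = ground_truth.labels == lab
        total += sel.sum()
        correct += (pred_species[sel] == name).sum()
    return correct / total


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
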