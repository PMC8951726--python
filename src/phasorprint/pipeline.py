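"""End-to-end orchestration: simulate → phasor → calibrate → filter →
fingerprint → classify, as one reproducible run with a written manifest.

A run simulates pure cubes for every library species plus a reference-
fluorophore cube, builds the fingerprint library through the Model/Results
layer, simulates the mixed scene (library species plus any interferents),
classifies it, and writes every artifact with content hashes next to the
effective configuration.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Union

from pydantic import BaseModel, Field

from . import __version__
from .filtering import FilterParams, apply_filters
from .fingerprint import save_library
from .io import (
    save_cube,
    save_labelmap,
    save_phasor,
    save_phasor_density_csv,
    save_render_png,
)
from .model import PhasorFingerprintModel
from .phasor import CalibrationRef, calibrate, phasor_transform
from .segment import particle_stats, particles_to_dataframe, render_pseudocolor
from .simulate import (
    NILE_RED_LIFETIME_NS,
    AcquisitionSpec,
    SceneSpec,
    SpeciesSpec,
    demo_scene,
    simulate_cube,
    simulate_uniform_cube,
    unstained_species,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("phasorprint")

# fixed seed offsets so every stage has an independent, reproducible stream
_SEED_REFERENCE = 101
_SEED_SPECIES = 200
_SEED_MIXTURE = 907


class PipelineConfig(BaseModel):
    """Fully serialisable description of one pipeline run."""

    out_dir: str = "phasorprint_run"
    acquisition: AcquisitionSpec = Field(default_factory=AcquisitionSpec)
    filters: FilterParams = Field(default_factory=FilterParams)
    harmonic: int = 2
    radius_k: float = 3.5
    reference_lifetime: float = NILE_RED_LIFETIME_NS
    library_species: List[SpeciesSpec] = Field(default_factory=list)
    interferents: List[SpeciesSpec] = Field(default_factory=list)
    scene: Optional[SceneSpec] = None
    library_shape: tuple = (64, 64)
    min_particle_size: int = 5

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


def demo_config(out_dir: str = "phasorprint_demo", seed: int = 1) -> PipelineConfig:
    """The shipped demo: four unstained microplastics plus one interferent.

    Reproduces, from simulation alone, a four-fingerprint library and a
    classified mixed scene with a non-plastic interferent particle.
    """
    species = [unstained_species(n) for n in ("ABS", "PET", "PVC", "PLA")]
    interferent = SpeciesSpec(
        name="sediment", components=[(4.5, 1.0)], brightness=1e4, color="gray"
    )
    scene = demo_scene(
        shape=(64, 64),
        include=("ABS", "PET", "PVC", "PLA"),
        interferents=("sediment",),
        diameter_um=28.0,
    )
    acq = AcquisitionSpec(seed=seed)
    return PipelineConfig(
        out_dir=out_dir,
        acquisition=acq,
        library_species=species,
        interferents=[interferent],
        scene=scene,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending path."""


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    acq = config.acquisition
    base_seed = acq.seed

    def record(path: Path) -> None:
        outputs[path.name] = _sha256(path)

    stage = "reference"
    try:
        log.info("simulating calibration reference (tau = %.2f ns)",
                 config.reference_lifetime)
        ref_species = SpeciesSpec(
            name="reference",
            components=[(config.reference_lifetime, 1.0)],
            brightness=1e4,
            color="orange",
        )
        ref_acq = acq.model_copy(update={"seed": base_seed + _SEED_REFERENCE})
        ref_cube = simulate_uniform_cube(ref_species, ref_acq, shape=config.library_shape)
        ref_img = phasor_transform(ref_cube, harmonic=config.harmonic)
        reference = CalibrationRef.from_image(ref_img, config.reference_lifetime)

        stage = "fingerprint-library"
        cubes = {}
        for i, sp in enumerate(config.library_species):
            sp_acq = acq.model_copy(update={"seed": base_seed + _SEED_SPECIES + i})
            cube = simulate_uniform_cube(sp, sp_acq, shape=config.library_shape)
            p = out / f"cube_{sp.name}.h5"
            save_cube(cube, p)
            record(p)
            cubes[sp.name] = cube
        model = PhasorFingerprintModel.from_cubes(
            cubes,
            harmonic=config.harmonic,
            reference=reference,
            filter_params=config.filters,
            colors={sp.name: sp.color for sp in config.library_species},
            radius_k=config.radius_k,
        )
        results = model.fit()
        lib_path = out / "library.json"
        save_library(results.library, lib_path)
        record(lib_path)
        (out / "fit_summary.txt").write_text(results.summary() + "\n")
        record(out / "fit_summary.txt")

        stage = "mixture"
        scene = config.scene or demo_scene()
        all_species = list(config.library_species) + list(config.interferents)
        mix_acq = acq.model_copy(update={"seed": base_seed + _SEED_MIXTURE})
        mix_cube = simulate_cube(scene, all_species, mix_acq)
        p = out / "cube_mixture.h5"
        save_cube(mix_cube, p)
        record(p)

        stage = "phasor"
        mix_img = phasor_transform(mix_cube, harmonic=config.harmonic)
        mix_img = calibrate(mix_img, reference)
        mix_img = apply_filters(mix_img, config.filters)
        p = out / "phasor_mixture.tif"
        save_phasor(mix_img, p)
        record(p)
        record(p.with_suffix(".json"))
        p = out / "phasor_density.csv"
        save_phasor_density_csv(mix_img, p)
        record(p)

        stage = "classify"
        label_map = results.classify(
            mix_img,
            pixel_size=scene.pixel_size,
            min_particle_size=config.min_particle_size,
        )
        p = out / "labels.tif"
        save_labelmap(label_map, p)
        record(p)
        record(p.with_suffix(".json"))
        rgb = render_pseudocolor(label_map, intensity=mix_img.intensity)
        p = out / "render.png"
        save_render_png(rgb, p)
        record(p)
        records = particle_stats(label_map)
        p = out / "particles.csv"
        particles_to_dataframe(records).to_csv(p, index=False)
        record(p)
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"stage {stage!r} failed in {out}: {exc}") from exc

    manifest = {
        "phasorprint_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "config_hash": config.config_hash(),
        "seed": base_seed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    return manifest
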