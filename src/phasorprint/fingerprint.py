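"""Phasor fingerprint libraries: build, persist and query species signatures.

A *fingerprint* is the characteristic phasor cluster of a pure species:
its intensity-weighted centroid (G, S), a cluster radius, and the fast
(phase) lifetime of the centroid.  A *fingerprint library* collects the
fingerprints of known species under one acquisition context (repetition
rate + harmonic) and is the reference against which mixed-sample pixels
are matched — the phasor analogue of an FTIR/Raman comparison database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .phasor import PhasorImage, phase_lifetime

__all__ = [
    "Fingerprint",
    "FingerprintLibrary",
    "build_fingerprint",
    "match_phasor",
    "save_library",
    "load_library",
    "LIBRARY_SCHEMA",
]

LIBRARY_SCHEMA = "phasorprint-fingerprint-library/1"

#: Default cluster-radius multiple of the pooled per-axis standard
#: deviation.  For an isotropic 2-D Gaussian cluster the squared distance
#: to the centroid is σ²·χ²₂, so a k·σ radius covers 1 − exp(−k²/2) of the
#: cluster's own pixels: 99.8% at k = 3.5 (k = 2 would leave 13.5% of a
#: pure species' pixels outside their own fingerprint).
DEFAULT_RADIUS_K = 3.5

#: Floor for degenerate (zero-scatter) clusters, in phasor units.
MIN_RADIUS = 1e-4


@dataclass(frozen=True)
class Fingerprint:
    """Phasor signature of one species."""

    species: str
    centroid: Tuple[float, float]
    radius: float
    tau_fast: float  # ns, phase lifetime of the centroid
    harmonic: int
    color: str = "white"
    n_pixels: int = 0

    def __post_init__(self) -> None:
        g, s = self.centroid
        # slack accommodates shot noise and the reference-calibration remap
        # of the discretisation circle; gross off-circle centroids still fail
        if np.hypot(g - 0.5, s) > 0.5 + 5e-3:
            raise ValueError(
                f"fingerprint centroid ({g:.4f}, {s:.4f}) lies outside the "
                "universal circle"
            )
        if self.radius <= 0:
            raise ValueError("fingerprint radius must be > 0")

    def distance(self, g: float, s: float) -> float:
        return float(np.hypot(g - self.centroid[0], s - self.centroid[1]))


@dataclass
class FingerprintLibrary:
    """A set of fingerprints sharing one acquisition context."""

    entries: List[Fingerprint] = field(default_factory=list)
    repetition_rate: float = 8.0e7
    harmonic: int = 2
    calibration: str = ""
    version: str = "1"

    def __post_init__(self) -> None:
        names = [f.species for f in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species in library: {names}")
        for f in self.entries:
            if f.harmonic != self.harmonic:
                raise ValueError(
                    f"fingerprint {f.species} harmonic {f.harmonic} != "
                    f"library harmonic {self.harmonic}"
                )

    @property
    def species(self) -> List[str]:
        return [f.species for f in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, species: str) -> Fingerprint:
        for f in self.entries:
            if f.species == species:
                return f
        raise KeyError(species)

    def add(self, fp: Fingerprint) -> None:
        if fp.species in self.species:
            raise ValueError(f"species {fp.species!r} already in library")
        if fp.harmonic != self.harmonic:
            raise ValueError("harmonic mismatch")
        self.entries.append(fp)


def build_fingerprint(
    image: PhasorImage,
    species: str,
    color: str = "white",
    radius_k: float = DEFAULT_RADIUS_K,
    min_radius: float = MIN_RADIUS,
    min_pixels: int = 10,
) -> Fingerprint:
    """Estimate a species fingerprint from a pure, calibrated phasor image.

    The centroid is the intensity-weighted mean (G, S) over valid pixels;
    the radius is ``radius_k`` times the pooled (intensity-weighted, per-
    axis) standard deviation about the centroid, floored at ``min_radius``
    for degenerate clusters; ``tau_fast`` is the phase lifetime of the
    centroid.
    """
    if not image.calibrated:
        raise ValueError("fingerprints must be built from calibrated phasor images")
    valid = image.mask
    n = int(valid.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} valid pixels (< {min_pixels}) for {species!r}")
    w = image.intensity[valid]
    g = image.G[valid]
    s = image.S[valid]
    cg = float(np.average(g, weights=w))
    cs = float(np.average(s, weights=w))
    var_g = float(np.average((g - cg) ** 2, weights=w))
    var_s = float(np.average((s - cs) ** 2, weights=w))
    pooled_sd = np.sqrt(0.5 * (var_g + var_s))
    radius = max(radius_k * pooled_sd, min_radius)
    tau = phase_lifetime(cg, cs, image.repetition_rate, image.harmonic)
    return Fingerprint(
        species=species,
        centroid=(cg, cs),
        radius=float(radius),
        tau_fast=float(tau),
        harmonic=image.harmonic,
        color=color,
        n_pixels=n,
    )


def match_phasor(
    point: Tuple[float, float],
    library: FingerprintLibrary,
    harmonic: Optional[int] = None,
) -> Optional[str]:
    """Match a phasor point to the nearest fingerprint within its radius.

    Returns the species whose centroid is nearest in Euclidean (G, S)
    distance, provided that distance does not exceed that fingerprint's
    radius; otherwise ``None``.  An exact distance tie between two
    fingerprints returns ``None`` — ambiguity is surfaced, never hidden.
    """
    if len(library) == 0:
        raise ValueError("empty fingerprint library")
    if harmonic is not None and harmonic != library.harmonic:
        raise ValueError(
            f"query harmonic {harmonic} != library harmonic {library.harmonic}"
        )
    g, s = point
    d = np.array([f.distance(g, s) for f in library.entries])
    i = int(np.argmin(d))
    if np.count_nonzero(d == d[i]) > 1:
        return None
    if d[i] <= library.entries[i].radius:
        return library.entries[i].species
    return None


def _fp_to_dict(fp: Fingerprint) -> dict:
    return {
        "species": fp.species,
        "centroid": list(fp.centroid),
        "radius": fp.radius,
        "tau_fast_ns": fp.tau_fast,
        "harmonic": fp.harmonic,
        "color": fp.color,
        "n_pixels": fp.n_pixels,
    }


def save_library(library: FingerprintLibrary, path: Union[str, Path]) -> None:
    """Write a library to schema-versioned JSON (lossless round-trip)."""
    doc = {
        "schema": LIBRARY_SCHEMA,
        "version": library.version,
        "repetition_rate_hz": library.repetition_rate,
        "harmonic": library.harmonic,
        "calibration": library.calibration,
        "entries": [_fp_to_dict(f) for f in library.entries],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_library(path: Union[str, Path]) -> FingerprintLibrary:
    """Load a JSON library, rejecting unknown schemas and invalid content."""
    doc = json.loads(Path(path).read_text())
    schema = doc.get("schema")
    if schema != LIBRARY_SCHEMA:
        raise ValueError(
            f"unsupported library schema {schema!r}; this build reads {LIBRARY_SCHEMA!r}"
        )
    entries = [
        Fingerprint(
            species=e["species"],
            centroid=tuple(e["centroid"]),
            radius=e["radius"],
            tau_fast=e["tau_fast_ns"],
            harmonic=e["harmonic"],
            color=e.get("color", "white"),
            n_pixels=e.get("n_pixels", 0),
        )
        for e in doc["entries"]
    ]
    return FingerprintLibrary(
        entries=entries,
        repetition_rate=doc["repetition_rate_hz"],
        harmonic=doc["harmonic"],
        calibration=doc.get("calibration", ""),
        version=doc.get("version", "1"),
    )
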