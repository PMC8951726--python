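"""Model/Results interface over fingerprint estimation.

`PhasorFingerprintModel` is constructed from pure-species data (decay
cubes or already-transformed phasor images); :meth:`fit` estimates each
species' phasor centroid, cluster radius and fast lifetime and returns a
:class:`FingerprintResults` carrying the estimates, their standard
errors, a ``summary()`` table, the persistable library, and
classification/plotting entry points for mixed scenes.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .filtering import FilterParams, apply_filters
from .fingerprint import (
    DEFAULT_RADIUS_K,
    Fingerprint,
    FingerprintLibrary,
    build_fingerprint,
)
from .phasor import (
    CalibrationRef,
    DecayCube,
    PhasorImage,
    calibrate,
    phase_lifetime,
    phasor_transform,
)
from .segment import LabelMap, classify_pixels

__all__ = ["PhasorFingerprintModel", "FingerprintResults"]


class PhasorFingerprintModel:
    """Estimates a phasor fingerprint library from pure-species images.

    Parameters
    ----------
    images : mapping of species name -> PhasorImage
        Calibrated, filtered phasor images of pure species, all sharing
        one acquisition context.
    colors : mapping of species name -> color, optional
    radius_k : float
        Cluster radius in pooled standard deviations (default 3.5).
    """

    def __init__(
        self,
        images: Mapping[str, PhasorImage],
        colors: Optional[Mapping[str, str]] = None,
        radius_k: float = DEFAULT_RADIUS_K,
    ) -> None:
        if not images:
            raise ValueError("at least one pure-species image is required")
        self.images = dict(images)
        self.colors = dict(colors or {})
        self.radius_k = radius_k
        first = next(iter(self.images.values()))
        for name, img in self.images.items():
            if img.harmonic != first.harmonic:
                raise ValueError(f"{name}: harmonic differs across species images")
            if abs(img.repetition_rate - first.repetition_rate) > 1e-6 * first.repetition_rate:
                raise ValueError(f"{name}: repetition rate differs across species images")
        self.harmonic = first.harmonic
        self.repetition_rate = first.repetition_rate

    @classmethod
    def from_cubes(
        cls,
        cubes: Mapping[str, DecayCube],
        harmonic: int = 2,
        reference: Optional[CalibrationRef] = None,
        filter_params: Optional[FilterParams] = None,
        colors: Optional[Mapping[str, str]] = None,
        radius_k: float = DEFAULT_RADIUS_K,
    ) -> "PhasorFingerprintModel":
        """Transform, calibrate and filter raw cubes, then build the model.

        ``reference`` defaults to the identity calibration (an ideal
        instrument); pass a :class:`CalibrationRef` measured from a
        reference-fluorophore cube to correct a real or simulated IRF.
        """
        filter_params = filter_params or FilterParams()
        images: Dict[str, PhasorImage] = {}
        for name, cube in cubes.items():
            img = phasor_transform(cube, harmonic=harmonic)
            ref = reference or CalibrationRef.identity(
                reference_lifetime=3.1,
                repetition_rate=cube.repetition_rate,
                harmonic=harmonic,
            )
            img = calibrate(img, ref)
            images[name] = apply_filters(img, filter_params)
        return cls(images, colors=colors, radius_k=radius_k)

    def fit(self, min_pixels: int = 10) -> "FingerprintResults":
        """Estimate all fingerprints and package them as results."""
        entries = []
        stats = []
        for name, img in self.images.items():
            fp = build_fingerprint(
                img,
                species=name,
                color=self.colors.get(name, "white"),
                radius_k=self.radius_k,
                min_pixels=min_pixels,
            )
            entries.append(fp)
            stats.append(self._uncertainty(img, fp))
        library = FingerprintLibrary(
            entries=entries,
            repetition_rate=self.repetition_rate,
            harmonic=self.harmonic,
            calibration="model-fit",
        )
        return FingerprintResults(self, library, pd.DataFrame(stats))

    def _uncertainty(self, img: PhasorImage, fp: Fingerprint) -> dict:
        """Weighted standard errors of the centroid and a delta-method SE of τ."""
        w = img.intensity[img.mask]
        g = img.G[img.mask]
        s = img.S[img.mask]
        n_eff = float(w.sum() ** 2 / (w ** 2).sum())
        cg, cs = fp.centroid
        se_g = float(np.sqrt(np.average((g - cg) ** 2, weights=w) / n_eff))
        se_s = float(np.sqrt(np.average((s - cs) ** 2, weights=w) / n_eff))
        omega = 2.0 * np.pi * self.repetition_rate * 1e-9
        # τ_φ = S/(nωG): first-order propagation, covariance neglected
        dt_dg = -cs / (self.harmonic * omega * cg * cg)
        dt_ds = 1.0 / (self.harmonic * omega * cg)
        se_tau = float(np.hypot(dt_dg * se_g, dt_ds * se_s))
        return {
            "species": fp.species,
            "tau_fast_ns": fp.tau_fast,
            "se_tau_ns": se_tau,
            "G": cg,
            "S": cs,
            "se_G": se_g,
            "se_S": se_s,
            "radius": fp.radius,
            "n_pixels": fp.n_pixels,
            "n_eff": n_eff,
        }


class FingerprintResults:
    """Fitted fingerprint library with uncertainties and downstream actions."""

    def __init__(
        self,
        model: PhasorFingerprintModel,
        library: FingerprintLibrary,
        params: pd.DataFrame,
    ) -> None:
        self.model = model
        self.library = library
        self.params = params.set_index("species")

    @property
    def tau_fast(self) -> pd.Series:
        """Fast (phase) lifetimes of the fitted fingerprints, ns."""
        return self.params["tau_fast_ns"]

    def summary(self) -> str:
        """Human-readable fit summary table."""
        cols = ["tau_fast_ns", "se_tau_ns", "G", "S", "se_G", "se_S", "radius", "n_pixels"]
        table = self.params[cols].copy()
        header = (
            "Phasor fingerprint library fit\n"
            f"  repetition rate: {self.library.repetition_rate/1e6:.1f} MHz, "
            f"harmonic: {self.library.harmonic}\n"
            f"  species: {len(self.library)}, radius rule: "
            f"{self.model.radius_k:.2f} x pooled SD\n"
        )
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            return header + table.to_string()

    def classify(
        self,
        image: PhasorImage,
        pixel_size: float = 1.0,
        min_particle_size: int = 5,
    ) -> LabelMap:
        """Classify a mixed-scene phasor image against the fitted library."""
        return classify_pixels(
            image, self.library, pixel_size=pixel_size,
            min_particle_size=min_particle_size,
        )

    def plot(self, ax=None, images: bool = True):
        """Phasor plot: universal semicircle, data density, fingerprint circles."""
        from .plotting import plot_phasor

        return plot_phasor(
            images=self.model.images if images else None,
            library=self.library,
            repetition_rate=self.library.repetition_rate,
            harmonic=self.library.harmonic,
            ax=ax,
        )
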