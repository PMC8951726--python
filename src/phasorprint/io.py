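"""File formats: HDF5 decay cubes, TIFF phasor/label images, CSV tables.

Container layouts
-----------------
Decay cube (HDF5): datasets ``/counts`` [rows, cols, bins] (unsigned int)
and optional ``/ground_truth`` [rows, cols] (int32); root attributes
``repetition_rate_hz``, ``bin_width_ns``, ``n_bins``, ``seed`` and
``spec`` (JSON text of the full provenance metadata).

Phasor image: multi-page float32 TIFF with pages G, S, intensity, mask,
plus a ``.json`` sidecar holding harmonic, calibration state, repetition
rate and the provenance/filter log.

Label map: single-page uint16 TIFF plus a ``.json`` sidecar with the
legend and the pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phasor import DecayCube, PhasorImage
from .segment import LabelMap

__all__ = [
    "save_cube",
    "load_cube",
    "save_phasor",
    "load_phasor",
    "phasor_density",
    "save_phasor_density_csv",
    "save_labelmap",
    "load_labelmap",
    "save_render_png",
]

PathLike = Union[str, Path]


def save_cube(cube: DecayCube, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts, compression="gzip", shuffle=True)
        if cube.ground_truth is not None:
            f.create_dataset("ground_truth", data=cube.ground_truth.labels)
            f.attrs["ground_truth_legend"] = json.dumps(
                {str(k): list(v) for k, v in cube.ground_truth.legend.items()}
            )
            f.attrs["ground_truth_pixel_size"] = cube.ground_truth.pixel_size
        f.attrs["repetition_rate_hz"] = cube.repetition_rate
        f.attrs["bin_width_ns"] = cube.bin_width
        f.attrs["n_bins"] = cube.n_bins
        f.attrs["seed"] = int(cube.metadata.get("seed", -1))
        f.attrs["spec"] = json.dumps(cube.metadata)


def load_cube(path: PathLike) -> DecayCube:
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        meta = json.loads(f.attrs.get("spec", "{}"))
        gt = None
        if "ground_truth" in f:
            legend = {
                int(k): tuple(v)
                for k, v in json.loads(f.attrs["ground_truth_legend"]).items()
            }
            gt = LabelMap(
                labels=f["ground_truth"][...],
                legend=legend,
                pixel_size=float(f.attrs.get("ground_truth_pixel_size", 1.0)),
            )
        return DecayCube(
            counts=counts,
            repetition_rate=float(f.attrs["repetition_rate_hz"]),
            bin_width=float(f.attrs["bin_width_ns"]),
            metadata=meta,
            ground_truth=gt,
        )


def save_phasor(image: PhasorImage, path: PathLike) -> None:
    path = Path(path)
    pages = np.stack(
        [
            image.G.astype(np.float32),
            image.S.astype(np.float32),
            image.intensity.astype(np.float32),
            image.mask.astype(np.float32),
        ]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "harmonic": image.harmonic,
        "repetition_rate_hz": image.repetition_rate,
        "calibrated": image.calibrated,
        "pages": ["G", "S", "intensity", "mask"],
        "metadata": image.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_phasor(path: PathLike) -> PhasorImage:
    path = Path(path)
    pages = tifffile.imread(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return PhasorImage(
        G=pages[0].astype(float),
        S=pages[1].astype(float),
        intensity=pages[2].astype(float),
        harmonic=int(side["harmonic"]),
        repetition_rate=float(side["repetition_rate_hz"]),
        calibrated=bool(side["calibrated"]),
        mask=pages[3] > 0.5,
        metadata=side.get("metadata", {}),
    )


def phasor_density(
    image: PhasorImage,
    bins: int = 128,
    g_range: Tuple[float, float] = (-0.05, 1.05),
    s_range: Tuple[float, float] = (-0.1, 0.65),
) -> pd.DataFrame:
    """Histogram of valid phasor points on a stated (G, S) grid.

    Returns the non-empty cells as a tidy table of bin centres and counts.
    """
    g = image.G[image.mask]
    s = image.S[image.mask]
    hist, ge, se = np.histogram2d(g, s, bins=bins, range=[g_range, s_range])
    gi, si = np.nonzero(hist)
    return pd.DataFrame(
        {
            "g": 0.5 * (ge[gi] + ge[gi + 1]),
            "s": 0.5 * (se[si] + se[si + 1]),
            "count": hist[gi, si].astype(int),
        }
    )


def save_phasor_density_csv(image: PhasorImage, path: PathLike, bins: int = 128) -> None:
    phasor_density(image, bins=bins).to_csv(path, index=False)


def save_labelmap(label_map: LabelMap, path: PathLike) -> None:
    path = Path(path)
    if label_map.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for uint16 TIFF")
    tifffile.imwrite(path, label_map.labels.astype(np.uint16))
    sidecar = {
        "legend": {str(k): list(v) for k, v in label_map.legend.items()},
        "pixel_size_um": label_map.pixel_size,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_labelmap(path: PathLike) -> LabelMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    side = json.loads(path.with_suffix(".json").read_text())
    legend = {int(k): tuple(v) for k, v in side["legend"].items()}
    return LabelMap(labels=labels, legend=legend, pixel_size=side["pixel_size_um"])


def save_render_png(rgb: np.ndarray, path: PathLike) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8), extension=".png")
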