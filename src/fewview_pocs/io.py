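"""Text, TIFF and PNG I/O for sinograms, images and phantom specs.

Sinograms travel as whitespace-delimited text (one view per row) written at
17 significant digits, which round-trips IEEE doubles exactly.  Images are
written either as float TIFF (full precision) or as windowed 8-bit PNG for
display; the default window is [0, 1.59].  Phantom specs are YAML files
listing discs as ``(cx, cy, radius, value)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image as PILImage

from .geometry import Image2D, ParallelGeometry, Sinogram
from .phantom import Disc, DiscPhantomSpec

__all__ = [
    "write_sinogram_text",
    "read_sinogram_text",
    "write_tiff",
    "read_tiff",
    "write_png",
    "write_phantom_spec",
    "read_phantom_spec",
]

DISPLAY_WINDOW = (0.0, 1.59)


def write_sinogram_text(path: str | Path, sino: Sinogram) -> None:
    np.savetxt(path, sino.data, fmt="%.17g")


def read_sinogram_text(path: str | Path, geometry: ParallelGeometry) -> Sinogram:
    data = np.atleast_2d(np.loadtxt(path))
    return Sinogram(data, geometry)


def write_tiff(path: str | Path, image: Image2D | np.ndarray) -> None:
    data = image.data if isinstance(image, Image2D) else np.asarray(image)
    tifffile.imwrite(path, data.astype(np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_png(
    path: str | Path,
    image: Image2D | np.ndarray,
    window: tuple[float, float] = DISPLAY_WINDOW,
) -> None:
    """8-bit grayscale PNG with an explicit display window."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy hi > lo")
    data = image.data if isinstance(image, Image2D) else np.asarray(image)
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    PILImage.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(path)


def write_phantom_spec(path: str | Path, spec: DiscPhantomSpec) -> None:
    doc = {
        "overlap_mode": spec.overlap_mode,
        "discs": [
            {"cx": float(d.cx), "cy": float(d.cy),
             "radius": float(d.radius), "value": float(d.value)}
            for d in spec.discs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_phantom_spec(path: str | Path) -> DiscPhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    discs = tuple(
        Disc(float(d["cx"]), float(d["cy"]), float(d["radius"]), float(d["value"]))
        for d in doc["discs"]
    )
    return DiscPhantomSpec(discs, overlap_mode=doc.get("overlap_mode", "replace"))
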