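"""Reading and writing the package's on-disk formats.

Images travel as TIFF/PNG (via tifffile / Pillow through scikit-image);
height maps as TIFF or whitespace-delimited text matrices with a JSON
sidecar carrying the pixel spacing; force curves as two-column TSV
(z_nm, deflection_nm) with a grid manifest JSON; masks as 8-bit PNG label
images with a JSON legend; spectra and tables as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage import io as skio

from .afm_topo import HeightMap, RadialSpectrum
from .forcespec import Cantilever, ForceCurve
from .histoseg import Compartment, SegmentationMask

__all__ = [
    "read_image", "write_image", "read_heightmap", "write_heightmap",
    "read_force_grid", "write_force_grid", "write_mask", "read_mask",
    "write_spectrum",
]


def read_image(path) -> np.ndarray:
    return skio.imread(str(path))


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype in (np.float32, np.float64):
        image = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    skio.imsave(str(path), image, check_contrast=False)


def write_heightmap(path, hmap: HeightMap) -> None:
    """Text matrix (nm) plus a JSON sidecar with the pixel spacing."""
    path = Path(path)
    np.savetxt(path, hmap.heights, fmt="%.4f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"pixel_spacing_nm": hmap.pixel_spacing, "units": "nm"}) + "\n"
    )


def read_heightmap(path, pixel_spacing: float | None = None) -> HeightMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = skio.imread(str(path)).astype(float)
    else:
        heights = np.loadtxt(path)
    if pixel_spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError("pixel spacing missing: pass it or provide a sidecar")
        pixel_spacing = json.loads(sidecar.read_text())["pixel_spacing_nm"]
    return HeightMap(heights=heights, pixel_spacing=float(pixel_spacing))


def write_force_grid(
    directory, curves: list[ForceCurve], region_size_um: float,
    cantilever: Cantilever,
) -> None:
    """One TSV per point plus a manifest JSON for the whole grid."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = int(round(np.sqrt(len(curves))))
    for i, curve in enumerate(curves):
        np.savetxt(
            directory / f"point_{i:04d}.tsv",
            np.column_stack([curve.z, curve.deflection]),
            fmt="%.6f", delimiter="\t", header="z_nm\tdeflection_nm",
        )
    manifest = {
        "n_points": len(curves),
        "grid_n": n,
        "region_size_um": region_size_um,
        "cantilever": {
            "spring_constant_n_per_m": cantilever.spring_constant,
            "tip_radius_um": cantilever.tip_radius,
            "geometry": cantilever.geometry,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_force_grid(directory) -> tuple[list[ForceCurve], float, Cantilever]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cant = Cantilever(
        spring_constant=manifest["cantilever"]["spring_constant_n_per_m"],
        tip_radius=manifest["cantilever"]["tip_radius_um"],
    )
    curves = []
    for i in range(manifest["n_points"]):
        data = np.loadtxt(directory / f"point_{i:04d}.tsv", delimiter="\t")
        curves.append(ForceCurve(z=data[:, 0], deflection=data[:, 1]))
    return curves, float(manifest["region_size_um"]), cant


def write_mask(path, mask: SegmentationMask) -> None:
    """8-bit PNG label image with a JSON legend sidecar."""
    path = Path(path)
    skio.imsave(str(path), mask.labels, check_contrast=False)
    legend = {c.name.lower(): int(c) for c in Compartment}
    legend["pixel_size_um"] = mask.pixel_size
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(legend, indent=2) + "\n"
    )


def read_mask(path) -> SegmentationMask:
    path = Path(path)
    labels = skio.imread(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    pixel_size = 0.46
    if sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um", 0.46)
    return SegmentationMask(labels=labels, pixel_size=pixel_size)


def write_spectrum(path, spectrum: RadialSpectrum) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.freq, spectrum.power]),
        fmt="%.8g", delimiter="\t", header="freq_nm^-1\tpower",
    )
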