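"""Readers and writers for slices, phantoms and result tables.

Slices can be read from single-frame CT DICOM files (rescale slope and
intercept applied to recover HU) or from 8/16-bit PNG/TIFF rasters with
a declared affine HU mapping.  Phantoms are written as 16-bit TIFF with
HU offset by +1024 (so air at -1000 HU stores as 24), ground-truth
label maps as 8-bit PNG, and the generating spec as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import MixtureParams
from .phantom import AIR_HU, LabelMap, PhantomSpec, SliceImage

__all__ = [
    "read_dicom_slice",
    "read_raster_slice",
    "write_phantom",
    "read_phantom",
    "write_labelmap_png",
]

HU_TIFF_OFFSET = 1024.0
_LABEL_PNG_SCALE = 100  # label codes 0/1/2 -> 0/100/200 grey for visibility


def read_dicom_slice(path, mask_threshold_hu: float | None = None) -> SliceImage:
    """Read a single-frame CT DICOM slice as HU values.

    The modality rescale (slope, intercept) is applied.  If
    ``mask_threshold_hu`` is given, pixels at or below it (air) are
    masked out; otherwise all pixels are masked in.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    if mask_threshold_hu is None:
        mask = np.ones_like(hu, dtype=bool)
    else:
        mask = hu > mask_threshold_hu
    return SliceImage(pixels=hu, mask=mask)


def read_raster_slice(
    path,
    hu_origin: float = -1024.0,
    hu_per_level: float = 1.0,
    mask_threshold_hu: float | None = None,
) -> SliceImage:
    """Read an 8/16-bit PNG or TIFF raster with a declared HU mapping.

    Stored level L maps to ``hu_origin + hu_per_level * L``.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    hu = hu_origin + hu_per_level * arr.astype(float)
    if mask_threshold_hu is None:
        mask = np.ones_like(hu, dtype=bool)
    else:
        mask = hu > mask_threshold_hu
    return SliceImage(pixels=hu, mask=mask)


def _spec_to_dict(spec: PhantomSpec) -> dict:
    th = spec.theta_true
    return {
        "theta_true": {"e_f": th.e_f, "e_m": th.e_m, "s_f": th.s_f, "s_m": th.s_m, "z": th.z},
        "size": spec.size,
        "geometry": spec.geometry,
        "seed": spec.seed,
    }


def write_phantom(directory, stem: str, image: SliceImage, truth: LabelMap) -> dict:
    """Write a phantom as TIFF + label PNG + JSON sidecar; return paths."""
    import tifffile
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / f"{stem}.tif"
    png_path = directory / f"{stem}_labels.png"
    meta_path = directory / f"{stem}.json"

    stored = np.clip(image.pixels + HU_TIFF_OFFSET, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), stored)
    Image.fromarray((truth.labels * _LABEL_PNG_SCALE).astype(np.uint8)).save(png_path)
    meta = {"hu_offset": HU_TIFF_OFFSET}
    if image.provenance is not None:
        meta["spec"] = _spec_to_dict(image.provenance)
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"tiff": tiff_path, "labels": png_path, "meta": meta_path}


def read_phantom(directory, stem: str) -> tuple[SliceImage, LabelMap]:
    """Read back a phantom written by :func:`write_phantom`."""
    import tifffile
    from PIL import Image

    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    stored = tifffile.imread(str(directory / f"{stem}.tif")).astype(float)
    hu = stored - meta["hu_offset"]
    labels = (np.asarray(Image.open(directory / f"{stem}_labels.png")) // _LABEL_PNG_SCALE).astype(np.uint8)
    mask = labels != 0
    spec = None
    if "spec" in meta:
        sd = meta["spec"]
        spec = PhantomSpec(
            theta_true=MixtureParams(**sd["theta_true"]),
            size=sd["size"],
            geometry=sd["geometry"],
            seed=sd["seed"],
        )
    image = SliceImage(pixels=hu, mask=mask, provenance=spec)
    return image, LabelMap(labels=labels)


def write_labelmap_png(path, labels: LabelMap) -> None:
    """Write a quasi-segmentation result as an 8-bit PNG."""
    from PIL import Image

    Image.fromarray((labels.labels * _LABEL_PNG_SCALE).astype(np.uint8)).save(str(path))
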