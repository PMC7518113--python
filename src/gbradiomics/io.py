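"""Reading real-format inputs: grayscale images (PNG or single-frame DICOM)
and lesion contour files (JSON or CSV vertex lists)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import ConfigurationError, GrayscaleImage, LesionAnnotation

__all__ = ["load_image", "load_contour"]


def load_image(path: str | Path, pixel_spacing: float | None = None) -> GrayscaleImage:
    """Load an 8-bit grayscale image from PNG or single-frame DICOM.

    For PNG the pixel spacing must be supplied (images carry no calibration);
    for DICOM it is read from PixelSpacing (converted mm -> cm) unless
    overridden.  Uncalibrated images are rejected: the morphological features
    are meaningless without physical units.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ConfigurationError(f"{path}: expected a single-frame 2-D DICOM image")
        if pixel_spacing is None:
            spacing = getattr(ds, "PixelSpacing", None)
            if spacing is None:
                raise ConfigurationError(f"{path}: DICOM has no PixelSpacing and none was supplied")
            if abs(float(spacing[0]) - float(spacing[1])) > 1e-9:
                raise ConfigurationError(f"{path}: anisotropic PixelSpacing is not supported")
            pixel_spacing = float(spacing[0]) / 10.0  # mm -> cm
        arr = np.clip(arr, 0, 255)
    else:
        if pixel_spacing is None:
            raise ConfigurationError(f"{path}: pixel_spacing is required for non-DICOM images")
        arr = np.asarray(Image.open(path).convert("L"))
    return GrayscaleImage(arr, pixel_spacing=pixel_spacing)


def load_contour(path: str | Path, lesion_id: str | None = None,
                 patient_id: str | None = None, label: int | None = None) -> LesionAnnotation:
    """Load a lesion contour from a JSON vertex list or a two-column CSV.

    JSON files may carry ``lesion_id``/``patient_id``/``label`` alongside the
    ``vertices``; explicit arguments override file contents.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict):
            vertices = np.asarray(data["vertices"], dtype=float)
            lesion_id = lesion_id or data.get("lesion_id")
            patient_id = patient_id or data.get("patient_id")
            label = label if label is not None else data.get("label")
        else:
            vertices = np.asarray(data, dtype=float)
    else:
        frame = pd.read_csv(path)
        cols = [c.lower() for c in frame.columns]
        if "x" in cols and "y" in cols:
            vertices = frame[[frame.columns[cols.index("x")], frame.columns[cols.index("y")]]].to_numpy(float)
        else:
            vertices = frame.to_numpy(float)[:, :2]
    return LesionAnnotation(
        vertices,
        lesion_id=lesion_id or path.stem,
        patient_id=patient_id or path.stem,
        label=label,
    )
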