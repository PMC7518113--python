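"""Synthetic two-class B-mode ultrasound cohorts.

Generates grayscale images with lesion contours and class labels whose
extracted features carry the group structure the analysis assumes:

* class 0 (cholesterol polyp, pseudo polyp): smaller, more regular outline,
  slightly hypoechoic relative to class 1, with punctate hyperechoic foci
  clustered toward the lesion centre — the sonographic correlate of
  cholesterol crystals.  The foci make the within-lesion pixel distribution
  uneven (higher GLCM contrast/entropy, lower homogeneity/energy) and pull
  the high-intensity mask into a tight cluster (lower dispersion degree).
* class 1 (tubular adenoma, true polyp): larger, more irregular outline,
  texturally homogeneous speckle.

The appearance model is a proxy for B-mode imaging, not an acoustic
simulation: a piecewise-constant echogenicity map (background / lesion) is
softened, modulated by spatially correlated Rayleigh-type speckle, foci are
added, and the field is log-compressed to 8 bits.  Echo levels in the
configuration are targets on the compressed 0-255 scale; the generator
inverts the compression internally.

Lesion geometry is an ellipse with a low-order sinusoidal radial
perturbation, so the boundary is always a simple (star-shaped) polygon and
the irregularity amplitude directly controls solidity and perimeter excess.

Reproducibility: one master seed; each lesion draws from its own substream
keyed by (class, within-class index), so changing one class's size never
reshuffles the other lesions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .datatypes import ConfigurationError, GrayscaleImage, LesionAnnotation

__all__ = ["ClassParams", "CohortConfig", "SyntheticLesion", "generate_cohort", "write_cohort", "read_cohort"]

_N_VERTICES = 160
_MAX_RETRIES = 50


@dataclass
class ClassParams:
    """Generative parameters of one lesion class.

    maj_len_cm
        (mean, SD) of the truncated-normal major-axis length in cm.
    maj_len_range_cm
        Truncation interval of the major-axis length.
    axis_ratio
        (mean, SD) of the truncated-normal minor/major axis ratio.
    irregularity
        Amplitude of the low-order sinusoidal radial boundary perturbation
        (dimensionless, >= 0).
    foci_rate
        Expected (Poisson) count of punctate hyperechoic foci per lesion.
    foci_amplitude
        (low, high) uniform range of the foci brightness bump, linear scale.
    foci_sigma_px
        (low, high) uniform range of the Gaussian focus radius in pixels.
    foci_radial_extent
        Foci are placed at a fraction of the local boundary radius drawn
        uniformly in [0, foci_radial_extent]; < 1 clusters them centrally.
    echo_level
        Target mean lesion intensity on the compressed 0-255 scale.
    """

    maj_len_cm: tuple[float, float] = (0.971, 0.485)
    maj_len_range_cm: tuple[float, float] = (0.35, 2.0)
    axis_ratio: tuple[float, float] = (0.66, 0.10)
    irregularity: float = 0.03
    foci_rate: float = 8.0
    foci_amplitude: tuple[float, float] = (12.0, 30.0)
    foci_sigma_px: tuple[float, float] = (1.0, 2.0)
    foci_radial_extent: float = 0.7
    echo_level: float = 88.0


def _default_class1() -> ClassParams:
    return ClassParams(
        maj_len_cm=(1.738, 0.912),
        maj_len_range_cm=(0.5, 2.6),
        irregularity=0.12,
        foci_rate=0.0,
        echo_level=103.0,
    )


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults emulate the clinical study cohort the method was developed on:
    58 cholesterol polyps vs 41 tubular adenomas, lesion sizes anchored to
    that cohort's printed morphology summaries, at 0.02 cm/px on a 160 px
    frame.
    """

    n0: int = 58
    n1: int = 41
    image_size: int = 160
    pixel_spacing: float = 0.02
    class0: ClassParams = field(default_factory=ClassParams)
    class1: ClassParams = field(default_factory=_default_class1)
    background_level: float = 60.0
    speckle_scale: float = 2.2
    speckle_contrast: float = 0.10
    shading_amplitude: float = 0.12
    shading_scale: float = 14.0
    compression: float = 3.0
    frame_margin_px: int = 12
    paired_patients0: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 0 or self.n1 < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        if self.image_size <= 0:
            raise ConfigurationError(f"image_size must be positive, got {self.image_size}")
        if not self.pixel_spacing > 0:
            raise ConfigurationError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        for cp in (self.class0, self.class1):
            if cp.irregularity < 0 or cp.foci_rate < 0:
                raise ConfigurationError("irregularity and foci_rate must be >= 0")
        max_semi_px = max(
            self.class0.maj_len_range_cm[1], self.class1.maj_len_range_cm[1]
        ) / (2 * self.pixel_spacing)
        if self.image_size < 2 * (max_semi_px + self.frame_margin_px):
            raise ConfigurationError(
                "image_size too small for the largest admissible lesion plus frame margin"
            )

    @classmethod
    def null(cls, n0: int = 58, n1: int = 41, seed: int = 0, **kw) -> "CohortConfig":
        """A null cohort: both classes drawn from identical parameters."""
        shared = ClassParams()
        return cls(
            n0=n0,
            n1=n1,
            class0=shared,
            class1=dataclasses.replace(shared),
            seed=seed,
            **kw,
        )


@dataclass
class SyntheticLesion:
    """One generated lesion: image, contour annotation, label, and the sampled
    generative parameters (for diagnostics)."""

    image: GrayscaleImage
    contour: LesionAnnotation
    label: int
    true_params: dict | None = None


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(200):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _decompress(level: np.ndarray | float, gamma: float) -> np.ndarray | float:
    """Invert the log compression so post-compression levels hit their target."""
    return (np.expm1(np.asarray(level) / 255.0 * np.log1p(gamma))) * 255.0 / gamma


def _compress(field_: np.ndarray, gamma: float) -> np.ndarray:
    return 255.0 * np.log1p(gamma * np.clip(field_, 0.0, None) / 255.0) / np.log1p(gamma)


def _sample_contour(
    rng: np.random.Generator, params: ClassParams, cfg: CohortConfig
) -> tuple[np.ndarray, dict]:
    """Sample a star-shaped perturbed-ellipse contour that fits the frame."""
    size = cfg.image_size
    margin = cfg.frame_margin_px
    for _ in range(_MAX_RETRIES):
        maj_cm = _trunc_normal(rng, *params.maj_len_cm, *params.maj_len_range_cm)
        ratio = _trunc_normal(rng, *params.axis_ratio, 0.40, 0.92)
        a = maj_cm / 2.0 / cfg.pixel_spacing
        b = a * ratio
        phi = rng.uniform(-np.pi / 2, np.pi / 2)
        cx = size / 2.0 + rng.uniform(-8, 8)
        cy = size / 2.0 + rng.uniform(-8, 8)
        theta = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
        r0 = a * b / np.sqrt((b * np.cos(theta - phi)) ** 2 + (a * np.sin(theta - phi)) ** 2)
        pert = np.zeros_like(theta)
        for k in range(2, 6):
            pert += rng.normal(0.0, 1.0) / k * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
        radii = r0 * np.clip(1.0 + params.irregularity * pert, 0.55, None)
        xs = cx + radii * np.cos(theta)
        ys = cy + radii * np.sin(theta)
        if xs.min() >= margin and ys.min() >= margin and xs.max() <= size - 1 - margin and ys.max() <= size - 1 - margin:
            info = {"maj_len_cm": maj_cm, "axis_ratio": ratio, "phi_deg": float(np.degrees(phi)),
                    "center": (float(cx), float(cy)), "semi_axes_px": (float(a), float(b))}
            return np.column_stack([xs, ys]), info
    raise ConfigurationError(
        "could not fit a sampled lesion inside the frame; increase image_size"
    )


def _render_lesion(
    rng: np.random.Generator,
    vertices: np.ndarray,
    params: ClassParams,
    cfg: CohortConfig,
) -> tuple[np.ndarray, dict]:
    """Render the speckled, log-compressed 8-bit image for one contour."""
    from .masks import rasterize_contour  # local import to avoid a cycle at import time

    size = cfg.image_size
    gamma = cfg.compression
    ann = LesionAnnotation(vertices, lesion_id="tmp", patient_id="tmp")
    interior = rasterize_contour(ann, (size, size)).pixels

    level = np.full((size, size), _decompress(cfg.background_level, gamma), dtype=np.float64)
    level[interior] = _decompress(params.echo_level, gamma)
    level = gaussian_filter(level, sigma=1.5)

    raw = rng.rayleigh(scale=1.0, size=(size, size))
    smooth = gaussian_filter(raw, sigma=cfg.speckle_scale)
    smooth = (smooth - smooth.mean()) / smooth.std()
    speckle = np.clip(1.0 + cfg.speckle_contrast * smooth, 0.05, None)
    # large-scale multiplicative shading: depth-gain / beam inhomogeneity proxy
    shade = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=cfg.shading_scale)
    shade = (shade - shade.mean()) / shade.std()
    shade = np.clip(1.0 + cfg.shading_amplitude * shade, 0.05, None)
    img = level * speckle * shade

    n_foci = int(rng.poisson(params.foci_rate))
    ys_l, xs_l = np.nonzero(interior)
    c = (xs_l.mean(), ys_l.mean())
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_foci):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        # radial placement linear in U(0,1): foci concentrate toward the centre
        frac = params.foci_radial_extent * rng.uniform()
        rmax = _radius_at(vertices, c, ang)
        fx = c[0] + frac * rmax * np.cos(ang)
        fy = c[1] + frac * rmax * np.sin(ang)
        amp = rng.uniform(*params.foci_amplitude)
        sig = rng.uniform(*params.foci_sigma_px)
        img += amp * np.exp(-((xx - fx) ** 2 + (yy - fy) ** 2) / (2.0 * sig**2))

    out = np.clip(np.rint(_compress(img, gamma)), 0, 255).astype(np.uint8)
    return out, {"n_foci": n_foci}


def _radius_at(vertices: np.ndarray, center: tuple[float, float], angle: float) -> float:
    """Approximate boundary radius from the centroid along a direction."""
    dx = vertices[:, 0] - center[0]
    dy = vertices[:, 1] - center[1]
    ang = np.arctan2(dy, dx)
    k = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - angle))))))
    return float(np.hypot(dx[k], dy[k]))


def _patient_ids(cfg: CohortConfig) -> tuple[list[str], list[str]]:
    """Patient ids per class; a few class-0 patients carry two lesions, as in
    the clinical cohort (58 lesions in 55 patients)."""
    pairs = min(cfg.paired_patients0, cfg.n0 // 2)
    ids0 = []
    for i in range(cfg.n0):
        pid = i // 2 if i < 2 * pairs else i - pairs
        ids0.append(f"P0-{pid:03d}")
    ids1 = [f"P1-{i:03d}" for i in range(cfg.n1)]
    return ids0, ids1


def generate_cohort(config: CohortConfig) -> list[SyntheticLesion]:
    """Generate the full cohort: ``n0`` class-0 then ``n1`` class-1 lesions.

    Identical config and seed produce bit-identical images and contours.
    """
    ids0, ids1 = _patient_ids(config)
    lesions: list[SyntheticLesion] = []
    for label, n, params, pids in ((0, config.n0, config.class0, ids0), (1, config.n1, config.class1, ids1)):
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(label, i))
            )
            vertices, geom = _sample_contour(rng, params, config)
            pixels, render = _render_lesion(rng, vertices, params, config)
            lesion_id = f"L{label}-{i:03d}"
            ann = LesionAnnotation(vertices, lesion_id=lesion_id, patient_id=pids[i], label=label)
            img = GrayscaleImage(pixels, pixel_spacing=config.pixel_spacing)
            lesions.append(SyntheticLesion(img, ann, label, {**geom, **render}))
    return lesions


def write_cohort(cohort: list[SyntheticLesion], out_dir: str | Path) -> Path:
    """Write a cohort to disk: one 8-bit PNG and one contour JSON per lesion,
    plus a manifest CSV.  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for les in cohort:
        lid = les.contour.lesion_id
        img_file = f"{lid}.png"
        contour_file = f"{lid}.json"
        Image.fromarray(les.image.pixels, mode="L").save(out / img_file)
        with open(out / contour_file, "w") as fh:
            json.dump(
                {
                    "lesion_id": lid,
                    "patient_id": les.contour.patient_id,
                    "label": les.label,
                    "vertices": np.asarray(les.contour.vertices).tolist(),
                },
                fh,
            )
        rows.append(
            {
                "lesion_id": lid,
                "patient_id": les.contour.patient_id,
                "image_file": img_file,
                "contour_file": contour_file,
                "label": les.label,
                "pixel_spacing": les.image.pixel_spacing,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(
        rows,
        columns=["lesion_id", "patient_id", "image_file", "contour_file", "label", "pixel_spacing"],
    ).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SyntheticLesion]:
    """Read a cohort back from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    lesions = []
    for row in table.itertuples():
        pixels = np.asarray(Image.open(base / row.image_file).convert("L"))
        with open(base / row.contour_file) as fh:
            data = json.load(fh)
        ann = LesionAnnotation(
            np.asarray(data["vertices"], dtype=float),
            lesion_id=str(row.lesion_id),
            patient_id=str(row.patient_id),
            label=int(row.label),
        )
        img = GrayscaleImage(pixels, pixel_spacing=float(row.pixel_spacing))
        lesions.append(SyntheticLesion(img, ann, int(row.label)))
    return lesions
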