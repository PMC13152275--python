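"""SEM eggshell pore detection and quantification.

Surface SEM fields show pores as holes against a bright shell matrix:
functional pores (presumed to traverse the shell) are dark, while
occluded or superficial holes are lighter gray.  The detector
thresholds the normalized image, labels connected components
(8-connectivity), filters out tiny and border-touching components, and
classifies each remaining component by its mean interior intensity.
Areas are converted to μm² through the pixel scale, and pore density is
reported per mm² of field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "SEMImage",
    "Pore",
    "PoreSet",
    "DetectionParams",
    "normalize_image",
    "detect_pores",
    "summarize_structure",
    "EggshellStructureRecord",
]

DARK_THRESHOLD = 0.2       # mean interior intensity at or below -> functional
OCCLUDED_THRESHOLD = 0.5   # candidate mask cutoff; (dark, occluded] -> occluded
MIN_AREA_UM2 = 0.05


@dataclass
class SEMImage:
    """Calibrated grayscale SEM field with intensities in [0, 1]."""

    pixels: np.ndarray       # 2D float array in [0, 1]
    scale_um_per_px: float
    magnification: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]; normalize first")

    @property
    def field_area_um2(self) -> float:
        return self.pixels.size * self.scale_um_per_px ** 2


@dataclass
class Pore:
    centroid: tuple[float, float]  # (row, col), 0-based pixel coordinates
    pixel_count: int
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: float
    pore_class: str  # "functional" | "occluded"


@dataclass
class PoreSet:
    pores: list[Pore]
    field_area_um2: float

    @property
    def functional(self) -> list[Pore]:
        return [p for p in self.pores if p.pore_class == "functional"]

    @property
    def occluded(self) -> list[Pore]:
        return [p for p in self.pores if p.pore_class == "occluded"]

    @property
    def density_per_mm2(self) -> float:
        """Functional pores per mm² of field (10⁶ μm² = 1 mm²)."""
        return 1e6 * len(self.functional) / self.field_area_um2

    @property
    def mean_functional_area_um2(self) -> float:
        f = self.functional
        return float(np.mean([p.area_um2 for p in f])) if f else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "row": p.centroid[0], "col": p.centroid[1],
                "pixel_count": p.pixel_count, "area_um2": p.area_um2,
                "equivalent_diameter_um": p.equivalent_diameter_um,
                "mean_intensity": p.mean_intensity, "class": p.pore_class,
            }
            for p in self.pores
        ])


@dataclass
class DetectionParams:
    dark_threshold: float = DARK_THRESHOLD
    occluded_threshold: float = OCCLUDED_THRESHOLD
    min_area_um2: float = MIN_AREA_UM2
    discard_border: bool = True
    otsu: bool = False  # adaptive candidate threshold for real images
    #: candidate pixels must also sit this many robust SDs (1.4826*MAD)
    #: below the background median; guards against speckle detections in
    #: fields that contain no true dark content
    background_gate_sds: float = 6.0

    def __post_init__(self) -> None:
        if not self.dark_threshold < self.occluded_threshold:
            raise ValueError("dark threshold must be below occluded threshold")


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Robust linear rescale: 1st percentile → 0, 99th percentile → 1.

    Affine transforms of the input map to the same output, so detection
    downstream is invariant to brightness/contrast settings.  Constant
    images map to all-0.5 with a warning.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D array")
    lo, hi = np.percentile(arr, [1.0, 99.0])
    if hi <= lo:
        warnings.warn("constant image; returning all-0.5", stacklevel=2)
        return np.full_like(arr, 0.5)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def detect_pores(img: SEMImage, params: Optional[DetectionParams] = None) -> PoreSet:
    """Segment and classify pores in a normalized SEM field.

    Pipeline: candidate mask below the occluded threshold → connected
    components (8-connectivity) → drop components smaller than the
    minimum area or touching the border → classify by mean interior
    intensity (functional vs. occluded) → physical areas via the pixel
    scale.
    """
    params = params or DetectionParams()
    px = img.pixels
    if params.otsu:
        from skimage.filters import threshold_otsu
        cutoff = float(threshold_otsu(px))
    else:
        cutoff = params.occluded_threshold
    med = float(np.median(px))
    mad_sd = 1.4826 * float(np.median(np.abs(px - med)))
    gate = med - params.background_gate_sds * mad_sd
    mask = px < min(cutoff, gate)
    labels = measure.label(mask, connectivity=2)
    scale2 = img.scale_um_per_px ** 2
    min_px = params.min_area_um2 / scale2
    nrow, ncol = px.shape
    pores: list[Pore] = []
    for region in measure.regionprops(labels, intensity_image=px):
        if region.area < min_px:
            continue
        if params.discard_border:
            r0, c0, r1, c1 = region.bbox
            if r0 == 0 or c0 == 0 or r1 == nrow or c1 == ncol:
                continue
        mean_int = float(region.intensity_mean)
        if mean_int <= params.dark_threshold:
            cls = "functional"
        elif mean_int <= params.occluded_threshold:
            cls = "occluded"
        else:
            continue
        area = region.area * scale2
        pores.append(Pore(
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            pixel_count=int(region.area),
            area_um2=float(area),
            equivalent_diameter_um=float(2.0 * np.sqrt(area / np.pi)),
            mean_intensity=mean_int,
            pore_class=cls,
        ))
    return PoreSet(pores=pores, field_area_um2=img.field_area_um2)


@dataclass
class EggshellStructureRecord:
    species: str
    thickness_um: float
    thickness_replicates: list[float]
    pore_density_per_mm2: float
    density_replicates: list[float]
    pore_size_um2: float
    size_replicates: list[float]


def summarize_structure(
    species: str,
    thickness_replicates: Sequence[float],
    pore_sets: Sequence[PoreSet],
) -> EggshellStructureRecord:
    """Average replicate measurements (nominally three per specimen).

    Thickness replicates are manual linear measurements; pore density and
    mean pore size come from replicate SEM fields.  Fewer than three
    replicates are accepted with a warning; the raw triples are retained
    for downstream repeatability analysis.
    """
    if len(thickness_replicates) == 0 or len(pore_sets) == 0:
        raise ValueError("need at least one replicate of each measurement")
    if len(thickness_replicates) != 3 or len(pore_sets) != 3:
        warnings.warn(
            f"{species}: expected 3 replicates, got "
            f"{len(thickness_replicates)} thickness / {len(pore_sets)} image",
            stacklevel=2,
        )
    dens = [ps.density_per_mm2 for ps in pore_sets]
    sizes = [ps.mean_functional_area_um2 for ps in pore_sets]
    sizes_ok = [s for s in sizes if np.isfinite(s)]
    return EggshellStructureRecord(
        species=species,
        thickness_um=float(np.mean(thickness_replicates)),
        thickness_replicates=[float(t) for t in thickness_replicates],
        pore_density_per_mm2=float(np.mean(dens)),
        density_replicates=[float(d) for d in dens],
        pore_size_um2=float(np.mean(sizes_ok)) if sizes_ok else float("nan"),
        size_replicates=[float(s) for s in sizes],
    )
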