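"""Stained-section and lung-structure quantification.

Implements the three image-derived readouts used to score stained human
lung sections and elastase-injured precision-cut lung slices (PCLS):

* positive-area percentage of a chromogen (NovaRed) within tissue:
  ``Area(%) = Area(positive) / Area(total) * 100``;
* reciprocal mean staining intensity over positive pixels:
  ``255 - mean(intensity of positive pixels)`` on the 8-bit scale, so 0 is
  unstained-light and larger values mean darker (more) stain;
* mean linear intercept (LMI) stereology: parallel test lines are laid
  across a binary airspace mask, each maximal airspace run along a line is
  one chord, and the LMI of a field is the mean chord length in µm.
  Border-touching chords are excluded; five fields per animal are averaged
  by convention.

Chromogen isolation uses optical-density stain unmixing against a
two-vector color basis (chromogen + hematoxylin counterstain) followed by
Otsu (or fixed) thresholding within the tissue mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .organoids import ComparisonResult

__all__ = [
    "StainImage",
    "BinaryMask",
    "IhcQuant",
    "LmiResult",
    "DEFAULT_STAIN_VECTORS",
    "separate_stains",
    "tissue_mask",
    "positive_mask",
    "area_percent",
    "mean_reciprocal_intensity",
    "ihc_quantify",
    "lmi",
    "lmi_per_animal",
    "compare_lmi_paired",
]

# unit color (optical density) vectors: row 0 = hematoxylin counterstain,
# row 1 = red chromogen (NovaRed-like). Configurable everywhere they are used.
DEFAULT_STAIN_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin (blue-purple)
        [0.268, 0.709, 0.653],  # red chromogen (absorbs green/blue)
    ]
)


@dataclass
class StainImage:
    """8-bit RGB field with physical pixel size (µm/pixel)."""

    pixels: np.ndarray
    pixel_size: float
    field_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must be within [0, 255]")
            px = px.astype(np.uint8)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 µm/pixel")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Boolean H x W grid; ``semantics`` says what True means."""

    mask: np.ndarray
    semantics: str = "positive_stain"  # positive_stain | tissue | airspace

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.semantics not in ("positive_stain", "tissue", "airspace"):
            raise ValueError(f"unknown mask semantics {self.semantics!r}")
        self.mask = m.astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class IhcQuant:
    """Positive-area and reciprocal-intensity readout of one field."""

    area_percent: float
    mean_reciprocal_intensity: float | None
    n_positive_pixels: int
    threshold_used: float | None = None

    def __post_init__(self):
        if not 0 <= self.area_percent <= 100:
            raise ValueError("area_percent out of [0, 100]")
        if (self.n_positive_pixels == 0) != (self.area_percent == 0):
            raise ValueError("area_percent = 0 iff no positive pixels")

    def to_dict(self) -> dict:
        return {
            "area_percent": self.area_percent,
            "mean_reciprocal_intensity": self.mean_reciprocal_intensity,
            "n_positive_pixels": self.n_positive_pixels,
            "threshold_used": self.threshold_used,
        }


@dataclass
class LmiResult:
    """Mean-linear-intercept readout over one or more fields."""

    per_field_chords: list[list[float]]
    per_field_mean: list[float]
    overall_mean: float
    n_fields: int
    line_spacing: float
    orientation: str

    def to_dict(self) -> dict:
        return {
            "per_field_mean": self.per_field_mean,
            "overall_mean": self.overall_mean,
            "n_fields": self.n_fields,
            "line_spacing": self.line_spacing,
            "orientation": self.orientation,
            "n_chords": [len(c) for c in self.per_field_chords],
        }


def _optical_density(pixels: np.ndarray) -> np.ndarray:
    """Beer–Lambert transform: OD = -ln(I/255), with I clipped away from 0."""
    i = np.maximum(pixels.astype(float), 1.0)
    return -np.log(i / 255.0)


def separate_stains(
    image: StainImage, stain_vectors: np.ndarray = DEFAULT_STAIN_VECTORS
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB field into two per-pixel stain concentration channels.

    The image is converted to optical density and projected onto the two
    stain color vectors by least squares; concentrations are clamped at 0.
    Returns (channel for vector 0, channel for vector 1).
    """
    v = np.asarray(stain_vectors, dtype=float)
    if v.shape != (2, 3):
        raise ValueError("stain_vectors must be 2 x 3")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero stain vector")
    v = v / norms[:, None]
    if np.linalg.matrix_rank(v, tol=1e-6) < 2:
        raise ValueError("stain vectors are collinear")
    od = _optical_density(image.pixels).reshape(-1, 3)
    # least-squares concentrations: c = od @ V^+ with V (2x3)
    pinv = v.T @ np.linalg.inv(v @ v.T)
    conc = od @ pinv
    conc = np.clip(conc, 0.0, None)
    h, w = image.shape
    return conc[:, 0].reshape(h, w), conc[:, 1].reshape(h, w)


def tissue_mask(
    image: StainImage,
    luminance_fraction: float = 0.95,
    exclusion: BinaryMask | None = None,
) -> BinaryMask:
    """Non-background pixels: luminance below ``luminance_fraction`` of 255.

    An optional exclusion mask (True = exclude) removes manually annotated
    regions such as airway walls or vessels.
    """
    lum = image.pixels.astype(float).mean(axis=2)
    m = lum < luminance_fraction * 255.0
    if exclusion is not None:
        if exclusion.mask.shape != m.shape:
            raise ValueError("exclusion mask shape mismatch")
        m &= ~exclusion.mask
    return BinaryMask(m, semantics="tissue")


def positive_mask(
    channel: np.ndarray,
    tissue: BinaryMask,
    threshold: float | str = "otsu",
    min_concentration: float = 0.02,
) -> tuple[BinaryMask, float]:
    """Threshold a stain-concentration channel within the tissue mask.

    ``threshold='otsu'`` computes Otsu's threshold over tissue pixels only;
    a float applies a fixed cutoff. A constant channel (degenerate
    histogram) yields an empty positive mask under Otsu, and an Otsu
    threshold is never allowed below ``min_concentration`` — optical
    densities at the 8-bit quantization noise level (~1/255) are unstained,
    so an unstained field stays empty rather than being split on residual
    unmixing noise. Returns (mask, threshold used).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != tissue.mask.shape:
        raise ValueError("channel / tissue shape mismatch")
    if tissue.area_px == 0:
        raise ValueError("empty tissue mask")
    values = channel[tissue.mask]
    if threshold == "otsu":
        if np.ptp(values) == 0:
            return BinaryMask(np.zeros_like(tissue.mask), "positive_stain"), float(
                "nan"
            )
        t = max(float(threshold_otsu(values)), min_concentration)
    else:
        t = float(threshold)
    m = (channel > t) & tissue.mask
    return BinaryMask(m, semantics="positive_stain"), t


def area_percent(positive: BinaryMask, total: BinaryMask) -> float:
    """Positive-area percentage: 100 * |positive ∩ total| / |total|."""
    if positive.mask.shape != total.mask.shape:
        raise ValueError("mask shape mismatch")
    denom = total.area_px
    if denom == 0:
        raise ValueError("total mask is empty")
    num = int((positive.mask & total.mask).sum())
    return 100.0 * num / denom


def mean_reciprocal_intensity(
    channel: np.ndarray, positive: BinaryMask
) -> float | None:
    """255 minus the mean 8-bit intensity over positive pixels.

    On the source 8-bit convention 0 is darkest and 255 lightest, so the
    result grows with stain darkness. Returns None when no pixel is
    positive (undefined).
    """
    channel = np.asarray(channel)
    if channel.shape != positive.mask.shape:
        raise ValueError("channel / mask shape mismatch")
    if channel.min() < 0 or channel.max() > 255:
        raise ValueError("intensities must be within [0, 255]")
    if positive.area_px == 0:
        return None
    return float(255.0 - channel[positive.mask].astype(float).mean())


def ihc_quantify(
    image: StainImage,
    stain_vectors: np.ndarray = DEFAULT_STAIN_VECTORS,
    threshold: float | str = "otsu",
    luminance_fraction: float = 0.95,
    exclusion: BinaryMask | None = None,
) -> IhcQuant:
    """Full chromogen quantification of one field.

    Unmixes the chromogen channel (stain vector row 1), thresholds it
    within tissue, and reports positive-area percent plus the reciprocal
    mean intensity computed on the chromogen's 8-bit brightness (the
    lightness each positive pixel would have from the chromogen alone).
    """
    tissue = tissue_mask(image, luminance_fraction, exclusion)
    _, chromogen = separate_stains(image, stain_vectors)
    pos, t = positive_mask(chromogen, tissue, threshold)
    area = area_percent(pos, tissue)
    # 8-bit brightness attributable to the chromogen: I = 255 * exp(-c)
    brightness = np.clip(255.0 * np.exp(-chromogen), 0.0, 255.0)
    mri = mean_reciprocal_intensity(brightness, pos)
    return IhcQuant(
        area_percent=area,
        mean_reciprocal_intensity=mri,
        n_positive_pixels=pos.area_px,
        threshold_used=t,
    )


def _chords_along_axis(
    air: np.ndarray, axis: int, spacing_px: int
) -> list[int]:
    """Maximal airspace runs (pixel lengths) along test lines.

    Lines are rows (axis=0 steps across rows → horizontal lines) laid every
    ``spacing_px``; runs touching the image border are excluded.
    """
    if axis == 1:
        air = air.T
    h = air.shape[0]
    chords: list[int] = []
    for r in range(0, h, spacing_px):
        line = air[r]
        # run-length encode
        padded = np.concatenate(([False], line, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if s == 0 or e == line.size:  # touches border
                continue
            chords.append(int(e - s))
    return chords


def lmi(
    airspace: BinaryMask,
    pixel_size: float,
    line_spacing: float,
    orientation: str = "both",
) -> LmiResult:
    """Mean linear intercept of one field.

    Parallel test lines are laid every ``line_spacing`` µm (at least one
    pixel apart); every maximal run of airspace pixels along a line is one
    chord, converted to µm with ``pixel_size``. Chords touching the field
    border are excluded. ``orientation`` selects horizontal, vertical or
    both line families (default both, pooled).
    """
    if pixel_size <= 0 or line_spacing <= 0:
        raise ValueError("pixel_size and line_spacing must be > 0")
    if orientation not in ("horizontal", "vertical", "both"):
        raise ValueError("orientation must be horizontal | vertical | both")
    air = airspace.mask
    if not air.any() or air.all():
        raise ValueError("mask must contain both airspace and tissue")
    spacing_px = max(1, int(round(line_spacing / pixel_size)))
    chords_px: list[int] = []
    if orientation in ("horizontal", "both"):
        chords_px += _chords_along_axis(air, 0, spacing_px)
    if orientation in ("vertical", "both"):
        chords_px += _chords_along_axis(air, 1, spacing_px)
    chords = [c * pixel_size for c in chords_px]
    if not chords:
        warnings.warn("no valid chords in field (all touch the border?)",
                      stacklevel=2)
        mean = float("nan")
    else:
        mean = float(np.mean(chords))
    return LmiResult(
        per_field_chords=[chords],
        per_field_mean=[mean],
        overall_mean=mean,
        n_fields=1,
        line_spacing=line_spacing,
        orientation=orientation,
    )


def lmi_per_animal(fields: Sequence[LmiResult]) -> LmiResult:
    """Average per-field LMIs into one per-animal value (5 fields typical)."""
    if not fields:
        raise ValueError("need at least one field")
    n = sum(f.n_fields for f in fields)
    if n != 5:
        warnings.warn(
            f"LMI convention is 5 fields per animal; got {n}", stacklevel=2
        )
    means = [m for f in fields for m in f.per_field_mean]
    chords = [c for f in fields for c in f.per_field_chords]
    return LmiResult(
        per_field_chords=chords,
        per_field_mean=means,
        overall_mean=float(np.mean(means)),
        n_fields=n,
        line_spacing=fields[0].line_spacing,
        orientation=fields[0].orientation,
    )


def compare_lmi_paired(
    treated: Sequence[float],
    control: Sequence[float],
    animal_ids: Sequence[str] | None = None,
) -> ComparisonResult:
    """Paired comparison of per-animal LMI values (each animal its own control).

    Two-condition case: paired two-tailed t-test on within-animal
    differences. For more than two conditions use
    :func:`secrepair.organoids.anova_dunnett` with ``paired=True``.
    """
    t_arr = np.asarray(treated, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.size != c_arr.size or t_arr.size < 2:
        raise ValueError("need >= 2 matched animal pairs of equal length")
    if animal_ids is not None and len(set(animal_ids)) != t_arr.size:
        raise ValueError("animal ids must be unique and match pair count")
    d = t_arr - c_arr
    if np.ptp(d) == 0 and d[0] == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_rel(t_arr, c_arr)
    return ComparisonResult(
        group="treated",
        control="control",
        statistic=float(stat),
        p_raw=float(p),
        p_adjusted=None,
        alpha_adjusted=None,
        method="paired two-tailed t-test",
        n_per_group={"treated": int(t_arr.size), "control": int(c_arr.size)},
    )
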