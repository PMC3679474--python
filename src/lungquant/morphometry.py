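"""Automated mean linear intercept (L_M) morphometry for lung histology.

The mean linear intercept is a stereological estimate of mean airspace
dimension: a grid of horizontal test lines is laid over a binary
airspace/tissue mask and the number of airspace-to-tissue transitions
crossed by the lines is counted.  With ``N`` lines of length ``l`` (px)
and ``sum_I`` transitions,

    L_M = (N * l / sum_I) / px_per_micron   [micron]

The full per-image chain is: two-class K-means colour segmentation ->
removal of small white components (vessels, stray pixels) -> line grid ->
transition counting -> L_M.  Per-mouse values are unweighted means over
images; group summaries are mean +/- SEM over mice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights, used whenever a scalar intensity is needed.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default line spacing: 25 micron at 2.764 px/micron = 69 px.
DEFAULT_SPACING_PX = 69
#: White components below this area (px^2) are treated as non-airspace.
DEFAULT_MIN_AREA_PX = 500
#: Pixel calibration of the acquisition setup emulated by the generator.
DEFAULT_PX_PER_MICRON = 2.764


class MorphometryError(Exception):
    """Base class for morphometry failures."""


class DegenerateImageError(MorphometryError):
    """Raised when an image carries a single colour and K-means cannot split it."""


class NoInterceptsError(MorphometryError):
    """Raised when a mask produces zero airspace-to-tissue transitions."""


@dataclass(frozen=True)
class CalibratedImage:
    """RGB raster with a pixels-per-micron scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    px_per_micron: float = DEFAULT_PX_PER_MICRON

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if self.px_per_micron <= 0:
            raise ValueError("px_per_micron must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class AirspaceMask:
    """Binary raster: True = airspace (white space), False = tissue."""

    mask: np.ndarray  # (H, W) bool
    min_component_area_applied: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def airspace_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class LineGrid:
    """Horizontal test-line grid: rows at 0, spacing, 2*spacing, ..."""

    rows: np.ndarray  # strictly increasing row indices
    line_length_px: int  # l: each line spans the full image width
    spacing_px: int

    @property
    def n_lines(self) -> int:
        """N: the number of times the line is placed on the image."""
        return len(self.rows)

    @property
    def total_length_px(self) -> int:
        """N * l, the total test-line length in pixels."""
        return self.n_lines * self.line_length_px

    def total_length_um(self, px_per_micron: float) -> float:
        return self.total_length_px / px_per_micron


@dataclass(frozen=True)
class InterceptCounts:
    """Transition tally for one image: the symbols of the L_M equation."""

    n_lines: int  # N
    line_length_px: int  # l
    transitions: int  # sum_I, airspace -> tissue

    def __post_init__(self) -> None:
        if self.transitions < 0:
            raise ValueError("transitions must be non-negative")

    @property
    def total_length_px(self) -> int:
        return self.n_lines * self.line_length_px


@dataclass(frozen=True)
class MorphometryConfig:
    spacing_px: int = DEFAULT_SPACING_PX
    min_area_px: int = DEFAULT_MIN_AREA_PX
    px_per_micron: float | None = None  # None: take it from the image
    count_direction: Literal["air_to_tissue", "both"] = "air_to_tissue"

    def __post_init__(self) -> None:
        if self.spacing_px < 1:
            raise ValueError("spacing_px must be >= 1")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.count_direction not in ("air_to_tissue", "both"):
            raise ValueError("count_direction must be 'air_to_tissue' or 'both'")


@dataclass
class ImageMorphometry:
    """Per-image result with audit intermediates."""

    lm_um: float
    counts: InterceptCounts
    grid: LineGrid
    mask: AirspaceMask
    px_per_micron: float


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return rgb.astype(np.float64) @ LUMA_WEIGHTS


def segment_airspace(image: CalibratedImage, max_iter: int = 100) -> AirspaceMask:
    """Split an RGB image into airspace and tissue with two-class K-means.

    Pixels are clustered on their raw RGB vectors.  Initialisation is
    deterministic: centroids start at the darkest and brightest pixel
    colours (Rec. 601 luminance).  The cluster with the higher centroid
    luminance is labelled airspace.

    A single-colour image is degenerate (the two centroids coincide); it is
    resolved against a mid-grey reference: all-airspace if brighter than
    grey 127.5, all-tissue otherwise, and the mask is flagged.
    """
    pix = image.pixels.reshape(-1, 3).astype(np.float64)
    lum = pix @ LUMA_WEIGHTS
    i_dark = int(np.argmin(lum))
    i_bright = int(np.argmax(lum))
    c_dark = pix[i_dark]
    c_bright = pix[i_bright]

    if np.array_equal(c_dark, c_bright):
        # Degenerate: one colour only. Mid-grey (luminance 127.5) decides.
        is_air = float(lum[0]) > 127.5
        mask = np.full(image.pixels.shape[:2], is_air, dtype=bool)
        logger.warning(
            "single-colour image: resolved as %s via mid-grey reference",
            "all-airspace" if is_air else "all-tissue",
        )
        return AirspaceMask(mask=mask, degenerate=True)

    centroids = np.stack([c_dark, c_bright])
    labels = np.zeros(len(pix), dtype=np.int8)
    for _ in range(max_iter):
        d0 = ((pix - centroids[0]) ** 2).sum(axis=1)
        d1 = ((pix - centroids[1]) ** 2).sum(axis=1)
        new_labels = (d1 < d0).astype(np.int8)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in (0, 1):
            members = pix[labels == k]
            if len(members):  # empty cluster keeps its previous centroid
                centroids[k] = members.mean(axis=0)

    bright_cluster = int(np.argmax(centroids @ LUMA_WEIGHTS))
    mask = (labels == bright_cluster).reshape(image.pixels.shape[:2])
    return AirspaceMask(mask=mask)


def filter_small_airspaces(
    mask: AirspaceMask, min_area: int = DEFAULT_MIN_AREA_PX
) -> AirspaceMask:
    """Reassign airspace components smaller than ``min_area`` px to tissue.

    "Smaller than" is strict: a component of exactly ``min_area`` pixels is
    kept.  Components are 8-connected.  Tissue pixels never change class,
    so the operation is idempotent and never increases airspace area.
    """
    if min_area <= 1:
        return AirspaceMask(mask=mask.mask.copy(), min_component_area_applied=min_area,
                            degenerate=mask.degenerate)
    # max_size removes components of area <= max_size; strict "< min_area"
    # therefore maps to max_size = min_area - 1 (a 500-px component is kept).
    filtered = remove_small_objects(mask.mask, max_size=min_area - 1, connectivity=2)
    return AirspaceMask(
        mask=filtered, min_component_area_applied=min_area, degenerate=mask.degenerate
    )


def build_line_grid(height: int, width: int, spacing: int = DEFAULT_SPACING_PX) -> LineGrid:
    """Place horizontal lines at rows 0, spacing, 2*spacing, ... while row <= H-1.

    Each line spans the full image width, so l = W.  For a 1200-row image
    with 69-px spacing this yields N = 18 lines and N*l = 28,800 px of test
    line.  A spacing larger than the image still yields the single row 0.
    """
    if height < 1 or width < 1 or spacing < 1:
        raise ValueError("height, width and spacing must all be >= 1")
    rows = np.arange(0, height, spacing)
    return LineGrid(rows=rows, line_length_px=width, spacing_px=spacing)


def count_transitions(
    mask: AirspaceMask,
    grid: LineGrid,
    direction: Literal["air_to_tissue", "both"] = "air_to_tissue",
) -> InterceptCounts:
    """Count airspace-to-tissue transitions along the grid lines.

    Scanning left to right, a transition is a pixel that is airspace whose
    right neighbour is tissue.  Image borders are not transitions.  With
    ``direction='both'`` tissue-to-airspace crossings are counted too
    (conventional intercept counting); the default follows the strict
    one-directional rule.
    """
    if mask.mask.shape[1] != grid.line_length_px:
        raise ValueError("grid line length does not match mask width")
    if len(grid.rows) and grid.rows[-1] > mask.mask.shape[0] - 1:
        raise ValueError("grid rows exceed mask height")
    sub = mask.mask[grid.rows]
    if direction == "air_to_tissue":
        n = int((sub[:, :-1] & ~sub[:, 1:]).sum())
    elif direction == "both":
        n = int((sub[:, :-1] != sub[:, 1:]).sum())
    else:
        raise ValueError("direction must be 'air_to_tissue' or 'both'")
    return InterceptCounts(
        n_lines=grid.n_lines, line_length_px=grid.line_length_px, transitions=n
    )


def compute_mli(counts: InterceptCounts, px_per_micron: float) -> float:
    """L_M = (N * l / sum_I) / px_per_micron, in micron.

    Raises :class:`NoInterceptsError` when sum_I is zero (an all-airspace
    or all-tissue field has no defined intercept length).
    """
    if px_per_micron <= 0:
        raise ValueError("px_per_micron must be positive")
    if counts.transitions == 0:
        raise NoInterceptsError("no airspace-to-tissue transitions on the grid")
    return (counts.total_length_px / counts.transitions) / px_per_micron


def mli_for_image(
    image: CalibratedImage, config: MorphometryConfig | None = None
) -> ImageMorphometry:
    """Full per-image chain: segment -> filter -> grid -> count -> L_M."""
    cfg = config or MorphometryConfig()
    ppm = cfg.px_per_micron if cfg.px_per_micron is not None else image.px_per_micron
    try:
        mask = segment_airspace(image)
        mask = filter_small_airspaces(mask, cfg.min_area_px)
        grid = build_line_grid(image.height, image.width, cfg.spacing_px)
        counts = count_transitions(mask, grid, cfg.count_direction)
        lm = compute_mli(counts, ppm)
    except MorphometryError as exc:
        raise type(exc)(f"{exc} (stage: {type(exc).__name__})") from exc
    return ImageMorphometry(lm_um=lm, counts=counts, grid=grid, mask=mask, px_per_micron=ppm)


def aggregate(
    per_image: pd.DataFrame,
    value_col: str = "lm_um",
    mouse_col: str = "animal_id",
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse means and group mean +/- SEM over mouse-level values.

    ``per_image`` must map every image to a mouse and a group.  The
    per-mouse L_M is the unweighted mean over that mouse's images; group
    SEM uses the mouse-level sample SD (n-1 denominator) over n mice.
    Mice contributing zero valid images are simply absent (a warning is
    logged by the caller that dropped them).
    """
    required = {value_col, mouse_col, group_col}
    if not required.issubset(per_image.columns):
        raise ValueError(f"per-image table must have columns {sorted(required)}")
    per_mouse = (
        per_image.groupby([mouse_col, group_col], as_index=False)[value_col]
        .agg(["mean", "count"])
        .rename(columns={"mean": value_col, "count": "n_images"})
    )
    grp = per_mouse.groupby(group_col)[value_col]
    per_group = pd.DataFrame(
        {
            "mean": grp.mean(),
            "sem": grp.sem(ddof=1),
            "n": grp.count(),
        }
    ).reset_index()
    return per_mouse, per_group


def aggregate_image_level(
    per_image: pd.DataFrame,
    value_col: str = "lm_um",
    group_col: str = "group",
) -> pd.DataFrame:
    """Secondary aggregation treating each image as the unit (n = images)."""
    grp = per_image.groupby(group_col)[value_col]
    return pd.DataFrame(
        {"mean": grp.mean(), "sem": grp.sem(ddof=1), "n": grp.count()}
    ).reset_index()
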