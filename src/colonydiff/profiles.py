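"""Colony localization and line-profile densitometry.

The measurement geometry follows the densitometric protocol used for
colony-diffusion stacks: a line 512 pixels long and 10 pixels wide is drawn
through the axial diameter of the colony along the diffusion direction, and
the width-averaged intensity profile is read off every frame.  Relative
profiles divide each position by the mean intensity of a window upstream of
the colony (on the source side), which removes the unknown fluorescence
gain and exposes the in-colony fluorescent-volume deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .exceptions import ColonyNotFoundError, GeometryError
from .simulate import ImageStack

__all__ = [
    "LineSpec",
    "ColonyMask",
    "ProfileSeries",
    "RelativeProfile",
    "locate_colony",
    "default_line",
    "extract_profile",
    "relative_profile",
]

DEFAULT_LINE_LENGTH_PX = 512
DEFAULT_LINE_WIDTH_PX = 10


@dataclass(frozen=True)
class LineSpec:
    """Sampling line in pixel coordinates, (row, col) endpoints inclusive."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: int = DEFAULT_LINE_WIDTH_PX

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("line width must be >= 1 px")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def axis(self) -> tuple[float, float]:
        """Unit vector (row, col) along the diffusion direction."""
        d = np.array(self.end) - np.array(self.start)
        return tuple(d / np.linalg.norm(d))


@dataclass(frozen=True)
class ColonyMask:
    """Localized colony: center/radius in pixels plus the profile-axis
    boundary crossings in micrometers (measured from the source-side edge)."""

    center: tuple[float, float]  # (row, col), px
    radius: float  # px
    entry_x: float  # um
    exit_x: float  # um

    def __post_init__(self) -> None:
        if not self.entry_x < self.exit_x:
            raise GeometryError("entry_x must be smaller than exit_x")


@dataclass
class ProfileSeries:
    """Width-averaged line intensities per frame.

    ``intensities[i, j]`` is the mean intensity at time ``times[i]`` and
    position ``positions[j]`` (micrometers from the source-side sample of
    the line).
    """

    positions: np.ndarray
    times: np.ndarray
    intensities: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.intensities.shape != (len(self.times), len(self.positions)):
            raise ValueError("intensities must be (n_times, n_positions)")

    def row_at(self, t: float) -> np.ndarray:
        return self.intensities[int(np.argmin(np.abs(self.times - t)))]

    def time_at(self, t: float) -> float:
        return float(self.times[int(np.argmin(np.abs(self.times - t)))])

    def to_dataframe(self, mask: ColonyMask | None = None) -> pd.DataFrame:
        tt, xx = np.meshgrid(self.times, self.positions, indexing="ij")
        df = pd.DataFrame(
            {
                "time_s": tt.ravel(),
                "position_um": xx.ravel(),
                "intensity": self.intensities.ravel(),
            }
        )
        if mask is not None:
            region = np.where(
                df["position_um"] < mask.entry_x,
                "upstream",
                np.where(df["position_um"] > mask.exit_x, "downstream", "colony"),
            )
            df["region"] = region
        return df


@dataclass
class RelativeProfile:
    """Per-frame profile normalized by the upstream-window mean."""

    positions: np.ndarray
    ratio: np.ndarray
    upstream_mean: float
    upstream_window: tuple[float, float]
    time_s: float

    def colony_mean(self, mask: ColonyMask, buffer_um: float = 0.0) -> float:
        sel = (self.positions >= mask.entry_x + buffer_um) & (
            self.positions <= mask.exit_x - buffer_um
        )
        return float(np.mean(self.ratio[sel]))


def _fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit to (row, col) points."""
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    (cr, cc, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    r = np.sqrt(max(c + cr**2 + cc**2, 0.0))
    return float(cr), float(cc), float(r)


def locate_colony(
    stain_frame: np.ndarray,
    pixel_size: float,
    min_diameter_um: float = 10.0,
    axis: str = "rows",
) -> ColonyMask:
    """Segment the colony in a single stain-channel frame.

    Otsu threshold, morphological closing (the stain labels individual
    cells, which must be merged into one blob), hole filling, connected
    components, minimum-area filter, largest component, then a least-squares
    circle fit to the component boundary.  ``axis='rows'`` means the
    diffusion direction runs along image rows with the source on the left
    edge; entry/exit are where the default axial line crosses the fitted
    circle.

    Raises
    ------
    ColonyNotFoundError
        If no component reaches the minimum equivalent diameter.
    """
    frame = np.asarray(stain_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("stain_frame must be a single-channel 2-D image")
    if frame.max() <= frame.min():
        raise ColonyNotFoundError("no colony found: blank stain frame")

    binary = frame > filters.threshold_otsu(frame)
    binary = morphology.closing(binary, morphology.disk(3))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary)
    regions = measure.regionprops(labels, intensity_image=frame)
    min_area_px = np.pi * (0.5 * min_diameter_um / pixel_size) ** 2
    regions = [r for r in regions if r.area >= min_area_px]
    # contrast guard: a stained colony must stand well clear of the frame's
    # robust background level, or pure detector noise would segment
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    regions = [r for r in regions if r.intensity_mean > med + 10.0 * (mad + 1e-12)]
    if not regions:
        raise ColonyNotFoundError(
            f"no colony found: no sufficiently bright component above "
            f"{min_diameter_um:g} um equivalent diameter"
        )
    best = max(regions, key=lambda r: r.area)  # tie-break: larger area wins

    contours = measure.find_contours(labels == best.label, 0.5)
    boundary = max(contours, key=len)
    cr, cc, radius = _fit_circle(boundary)

    if axis == "rows":
        entry = (cc - radius) * pixel_size
        exit_ = (cc + radius) * pixel_size
    elif axis == "cols":
        entry = (cr - radius) * pixel_size
        exit_ = (cr + radius) * pixel_size
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    return ColonyMask(center=(cr, cc), radius=radius, entry_x=entry, exit_x=exit_)


def default_line(
    mask: ColonyMask, image_shape: tuple[int, int], width: int = DEFAULT_LINE_WIDTH_PX
) -> LineSpec:
    """The standard axial line: horizontal, through the colony center,
    spanning the full frame width (512 px for the default frame)."""
    h, w = image_shape
    row = float(np.clip(mask.center[0], 0, h - 1))
    return LineSpec(start=(row, 0.0), end=(row, float(w - 1)), width=width)


def extract_profile(stack: ImageStack, line: LineSpec, channel: int = 1) -> ProfileSeries:
    """Width-averaged intensity profiles along ``line`` for every frame.

    Intensity at sample i is the mean over ``line.width`` pixels
    perpendicular to the line (bilinear sampling); positions are micrometers
    from the first (source-side) sample of the line.
    """
    n_t, _, h, w = stack.frames.shape
    for r, c in (line.start, line.end):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise GeometryError(f"line endpoint ({r}, {c}) outside frame {h}x{w}")

    profiles = [
        measure.profile_line(
            stack.frames[k, channel].astype(float),
            line.start,
            line.end,
            linewidth=line.width,
            order=1,
            mode="constant",
            reduce_func=np.mean,
        )
        for k in range(n_t)
    ]
    intensities = np.asarray(profiles)
    positions = np.arange(intensities.shape[1]) * stack.pixel_size
    return ProfileSeries(
        positions=positions,
        times=np.asarray(stack.timestamps, dtype=float),
        intensities=intensities,
        pixel_size=stack.pixel_size,
    )


def relative_profile(
    series: ProfileSeries,
    mask: ColonyMask,
    frame_time: float,
    upstream_px: int = 20,
    buffer_px: int = 3,
    background: float = 0.0,
) -> RelativeProfile:
    """Relative-intensity profile at one frame.

    Each (background-subtracted) intensity is divided by the mean intensity
    of an upstream window of ``upstream_px`` pixels adjacent to the colony
    entry on the source side, separated from the rim by ``buffer_px`` pixels.
    """
    ps = series.pixel_size
    hi = mask.entry_x - buffer_px * ps
    lo = hi - upstream_px * ps
    lo = max(lo, series.positions[0])
    sel = (series.positions >= lo) & (series.positions <= hi)
    if sel.sum() < 5:
        raise GeometryError(
            f"upstream window [{lo:.1f}, {hi:.1f}] um holds only {int(sel.sum())} "
            "samples (minimum 5)"
        )
    row = series.row_at(frame_time) - background
    upstream_mean = float(np.mean(row[sel]))
    if upstream_mean <= 0:
        raise ValueError("upstream mean intensity is non-positive")
    return RelativeProfile(
        positions=series.positions,
        ratio=row / upstream_mean,
        upstream_mean=upstream_mean,
        upstream_window=(float(lo), float(hi)),
        time_s=series.time_at(frame_time),
    )
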