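"""Effective diffusion coefficients from linearized concentration profiles.

For a plane instantaneous source the concentration profile at time t is
Gaussian in x, so ln C(x) is linear in x^2 with slope -1/(4 D t).  An
ordinary least-squares fit of ln(intensity) against x^2 over a spatial
window therefore yields the effective diffusivity of that window:
D = -1 / (4 t slope).  Because fluorescence intensity is proportional to
concentration, any multiplicative gain (including the in-colony
fluorescent-volume fill factor) shifts only the intercept and leaves the
slope -- and hence D -- unchanged.

Two regions are fitted: the matrix outside the colony (upstream and
downstream windows pooled) giving D_out, and the colony interior giving
D_in.  The default fit time is 1800 s (30 min after the deposit), early
enough that the Gaussian short-time solution applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from .profiles import ColonyMask, ProfileSeries

__all__ = [
    "RegionFit",
    "DiffusionFit",
    "linearize",
    "fit_region",
    "estimate_din_dout",
]

DEFAULT_FIT_TIME_S = 1800.0
MIN_FIT_POINTS = 5


@dataclass
class RegionFit:
    """OLS fit of ln(intensity) vs x^2 over one region.

    ``slope`` is in 1/um^2, ``d_eff`` in um^2/s; a non-negative slope marks
    the fit as flagged and ``d_eff`` is NaN (undefined) rather than raising.
    """

    region: str
    slope: float
    intercept: float
    r2: float
    n_points: int
    fit_time: float
    n_dropped: int = 0

    @property
    def d_eff(self) -> float:
        if self.slope >= 0:
            return float("nan")
        return -1.0 / (4.0 * self.fit_time * self.slope)

    @property
    def flagged(self) -> bool:
        return self.slope >= 0

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "slope_per_um2": self.slope,
            "intercept": self.intercept,
            "d_eff_um2_per_s": self.d_eff,
            "r2": self.r2,
            "n_points": self.n_points,
            "n_dropped": self.n_dropped,
            "fit_time_s": self.fit_time,
            "flagged": self.flagged,
        }


@dataclass
class DiffusionFit:
    """Paired inside/outside fits and their ratio."""

    fit_in: RegionFit
    fit_out: RegionFit
    per_time_series: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def ratio_in_out(self) -> float:
        if self.fit_in.flagged or self.fit_out.flagged:
            return float("nan")
        return self.fit_in.d_eff / self.fit_out.d_eff


def linearize(
    series: ProfileSeries,
    region_window: tuple[float, float],
    fit_time: float = DEFAULT_FIT_TIME_S,
    background: float = 0.0,
    x_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired (x^2, ln intensity) samples in one spatial window.

    Positions are converted to physical distance from the deposit plane by
    adding ``x_offset`` (the window offset of the imaged frame).  Points
    whose background-subtracted intensity is non-positive cannot be
    log-transformed; they are dropped and counted in the returned tally.

    Returns
    -------
    (x_sq, ln_i, n_dropped)

    Raises
    ------
    InsufficientDataError
        If fewer than 5 usable points remain.
    """
    lo, hi = region_window
    sel = (series.positions >= lo) & (series.positions <= hi)
    x = series.positions[sel] + x_offset
    i = series.row_at(fit_time)[sel] - background
    usable = i > 0
    n_dropped = int((~usable).sum())
    if usable.sum() < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"only {int(usable.sum())} usable points in window [{lo:.1f}, {hi:.1f}] um "
            f"({n_dropped} non-positive dropped); need at least {MIN_FIT_POINTS}"
        )
    return x[usable] ** 2, np.log(i[usable]), n_dropped


def _ols(x_sq: np.ndarray, ln_i: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x_sq, ln_i)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def region_windows(
    mask: ColonyMask, series: ProfileSeries, buffer_px: int = 3
) -> dict[str, list[tuple[float, float]]]:
    """Spatial windows (um, profile coordinates) for each fit region.

    The colony interior excludes a rim buffer of ``buffer_px`` pixels; the
    matrix is split into an upstream (source-side) and a downstream
    segment, both buffered from the rim.
    """
    ps = series.pixel_size
    buf = buffer_px * ps
    x0, x1 = float(series.positions[0]), float(series.positions[-1])
    return {
        "inside": [(mask.entry_x + buf, mask.exit_x - buf)],
        "upstream": [(x0, mask.entry_x - buf)],
        "downstream": [(mask.exit_x + buf, x1)],
    }


def fit_region(
    series: ProfileSeries,
    mask: ColonyMask,
    region: str,
    fit_time: float = DEFAULT_FIT_TIME_S,
    background: float = 0.0,
    x_offset: float = 0.0,
    buffer_px: int = 3,
    outside_mode: str = "upstream",
) -> RegionFit:
    """OLS fit of ln(intensity) vs x^2 for the inside or outside region.

    Raw (not relative) intensities are used; slope scale-invariance makes
    the two equivalent up to the intercept.  ``outside_mode`` selects the
    matrix windows backing the outside fit: ``"upstream"`` (default) uses
    the source-side segment only, whose local flux perturbation by the
    colony matches the interior's and therefore cancels in the in/out
    ratio; ``"downstream"`` uses the far segment; ``"pooled"`` concatenates
    both (in a strictly one-dimensional medium the colony transmits reduced
    flux, so the downstream segment sits on a lower intensity branch and
    pooling biases the slope steep).
    """
    if region not in ("inside", "outside"):
        raise ValueError("region must be 'inside' or 'outside'")
    all_windows = region_windows(mask, series, buffer_px=buffer_px)
    if region == "inside":
        windows = all_windows["inside"]
    elif outside_mode == "pooled":
        windows = all_windows["upstream"] + all_windows["downstream"]
    elif outside_mode in ("upstream", "downstream"):
        windows = all_windows[outside_mode]
    else:
        raise ValueError("outside_mode must be 'upstream', 'downstream' or 'pooled'")
    xs, ys, dropped = [], [], 0
    err: InsufficientDataError | None = None
    for win in windows:
        try:
            x_sq, ln_i, n_drop = linearize(
                series, win, fit_time=fit_time, background=background, x_offset=x_offset
            )
        except InsufficientDataError as e:
            err = e
            continue
        xs.append(x_sq)
        ys.append(ln_i)
        dropped += n_drop
    if not xs:
        raise err if err is not None else InsufficientDataError(
            f"no usable windows for region {region!r}"
        )
    x_sq = np.concatenate(xs)
    ln_i = np.concatenate(ys)
    if len(x_sq) < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"only {len(x_sq)} usable points for region {region!r}"
        )
    slope, intercept, r2 = _ols(x_sq, ln_i)
    return RegionFit(
        region=region,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_points=len(x_sq),
        fit_time=float(series.time_at(fit_time)),
        n_dropped=dropped,
    )


def estimate_din_dout(
    series: ProfileSeries,
    mask: ColonyMask,
    fit_time: float = DEFAULT_FIT_TIME_S,
    background: float = 0.0,
    x_offset: float = 0.0,
    buffer_px: int = 3,
    outside_mode: str = "upstream",
    per_time_qc: bool = False,
) -> DiffusionFit:
    """Estimate D_in and D_out and their ratio from one profile series.

    With ``per_time_qc`` a per-frame (time, d_in, d_out) series is attached
    for quality control; the headline numbers always come from the single
    frame nearest ``fit_time``.
    """
    kwargs = dict(
        background=background,
        x_offset=x_offset,
        buffer_px=buffer_px,
        outside_mode=outside_mode,
    )
    fit_in = fit_region(series, mask, "inside", fit_time=fit_time, **kwargs)
    fit_out = fit_region(series, mask, "outside", fit_time=fit_time, **kwargs)
    qc: list[tuple[float, float, float]] = []
    if per_time_qc:
        for t in series.times:
            try:
                fi = fit_region(series, mask, "inside", fit_time=float(t), **kwargs)
                fo = fit_region(series, mask, "outside", fit_time=float(t), **kwargs)
            except InsufficientDataError:
                continue
            qc.append((float(t), fi.d_eff, fo.d_eff))
    return DiffusionFit(fit_in=fit_in, fit_out=fit_out, per_time_series=qc)
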