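"""Forward model: 1-D solute diffusion past a bacterial colony, rendered
as two-channel time-lapse confocal-like image stacks with known ground truth.

The physical picture is a fluorescent solute deposited at time zero as an
instantaneous plane source on the surface of a gel (a renneted skim-milk
"model cheese"), diffusing along the axis perpendicular to that surface.
A spherical bacterial colony embedded in the gel has a distinct effective
diffusivity ``d_in`` relative to the surrounding matrix ``d_out``; inside
the colony only a fraction of the volume (``fill_fraction``) is occupied by
fluorescent extracellular liquid, the remainder by non-fluorescent cells.

Physics is one-dimensional (plane front); rendering is two-dimensional
(the colony's equatorial cross-section in the imaging plane).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import ConfigurationError, GeometryError, UnknownScenarioError

__all__ = [
    "SimulationConfig",
    "ConcentrationField",
    "ColonyGeometry",
    "ImageStack",
    "GroundTruth",
    "plane_source_profile",
    "solve_diffusion",
    "render_stack",
    "simulate_scenario",
    "make_fixture",
    "list_scenarios",
    "SCENARIOS",
]

# Courant-type safety factor for the explicit scheme: solver time step is
# chosen as STABILITY_FACTOR * dx^2 / max(D); 0.5 is the stability limit.
STABILITY_FACTOR = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one forward-simulation run.

    Lengths in micrometers, times in seconds, diffusivities in um^2/s.

    Parameters
    ----------
    domain_length :
        Extent of the 1-D solved domain from the deposit plane (x = 0).
    grid_spacing :
        Finite-volume cell width of the solver grid.
    deposit_mass :
        Amount of solute (arbitrary fluorescence-mass units per unit area)
        deposited in the first grid cell at t = 0.
    d_out, d_in :
        Effective diffusivities of the matrix and of the colony interior.
    colony_center_x, colony_radius :
        Position (distance from the deposit plane) and equatorial radius of
        the colony.
    fill_fraction :
        Fraction of in-colony volume occupied by fluorescent liquid; the
        complement is rendered as non-fluorescent cell disks.
    frame_interval, first_frame_time, total_time :
        Acquisition timing; frames at first_frame_time, then every
        frame_interval until total_time.
    pixel_size, image_shape :
        Rendering geometry of the camera frame.
    window_offset :
        Distance from the deposit plane to the source-side edge of the
        imaged window.
    noise_sigma :
        Scale of multiplicative Gaussian detector noise.
    background_level :
        Additive detector offset, in counts.
    bit_depth :
        Output quantization (8 -> uint8 counts in [0, 255]).
    psf_sigma :
        Lateral point-spread-function width (um, Gaussian sigma) applied to
        the noise-free image; models confocal optical blur, which smooths
        the hard cell-disk edges the way real micrographs are smoothed.
    seed :
        Seed for detector noise (cell placement is seeded separately via
        :class:`ColonyGeometry`).
    solver_dt :
        Optional explicit solver time step; validated against the stability
        bound. When None (default) a stable step is chosen automatically.
    """

    domain_length: float = 800.0
    grid_spacing: float = 1.0
    deposit_mass: float = 1.0
    d_out: float = 4.0
    d_in: float = 2.0
    colony_center_x: float = 198.0
    colony_radius: float = 16.0
    fill_fraction: float = 0.5
    frame_interval: float = 300.0
    first_frame_time: float = 600.0
    total_time: float = 9000.0
    pixel_size: float = 0.62
    image_shape: tuple[int, int] = (512, 512)
    window_offset: float = 40.0
    noise_sigma: float = 0.05
    background_level: float = 5.0
    bit_depth: int = 8
    psf_sigma: float = 0.5
    seed: int = 0
    solver_dt: float | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if self.d_in <= 0 or self.d_out <= 0:
            raise ConfigurationError("diffusivities must be positive")
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ConfigurationError("fill_fraction must lie in (0, 1]")
        if self.deposit_mass < 0:
            raise ConfigurationError("deposit_mass must be non-negative")
        if self.colony_radius > 0:
            lo = self.colony_center_x - self.colony_radius
            hi = self.colony_center_x + self.colony_radius
            if not (0.0 < lo and hi < self.domain_length):
                raise GeometryError(
                    f"colony [{lo:.1f}, {hi:.1f}] um must lie strictly inside "
                    f"the domain (0, {self.domain_length:.1f}) um"
                )
        if self.first_frame_time <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("frame times must be positive")
        if self.total_time < self.first_frame_time:
            raise ConfigurationError("total_time must reach first_frame_time")
        if self.solver_dt is not None:
            dmax = max(self.d_in, self.d_out)
            limit = 0.5 * self.grid_spacing**2 / dmax
            if self.solver_dt > limit:
                raise ConfigurationError(
                    "explicit-scheme stability violated: "
                    f"max(D)*dt/dx^2 = {dmax * self.solver_dt / self.grid_spacing**2:.3f} "
                    f"> 0.5 (dt = {self.solver_dt:.4g} s, dx = {self.grid_spacing:.4g} um)"
                )

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition times in seconds, strictly increasing."""
        return np.arange(
            self.first_frame_time, self.total_time + 1e-9, self.frame_interval
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ConcentrationField:
    """Gridded solution C(x, t) of the 1-D diffusion problem.

    ``values[i, j]`` is the concentration at time ``t_grid[i]`` and cell
    center ``x_grid[j]``, in deposit-mass units per micrometer.
    """

    x_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray

    def at_time(self, t: float) -> np.ndarray:
        """Profile at the frame time closest to ``t``."""
        i = int(np.argmin(np.abs(self.t_grid - t)))
        return self.values[i]

    def mass(self) -> np.ndarray:
        """Trapezoidal mass integral per frame.

        The grid is extended to the domain boundaries with zero-gradient
        edge values (the no-flux condition) before integrating; on the
        cell-centered grid this quadrature is exact for the finite-volume
        solution, so conservation holds to round-off.
        """
        dx = self.x_grid[1] - self.x_grid[0] if len(self.x_grid) > 1 else 1.0
        x = np.concatenate([[self.x_grid[0] - 0.5 * dx], self.x_grid,
                            [self.x_grid[-1] + 0.5 * dx]])
        v = np.concatenate(
            [self.values[:, :1], self.values, self.values[:, -1:]], axis=1
        )
        return np.trapezoid(v, x, axis=1)


@dataclass(frozen=True)
class ColonyGeometry:
    """Placement of the colony cross-section in the image frame.

    ``center`` is (x, y) in micrometers in image coordinates (x along the
    diffusion axis measured from the source-side image edge, y across).
    """

    center: tuple[float, float]
    radius: float
    cell_seed: int = 0
    cell_radius: float = 0.5
    packing_fraction: float = 0.5

    def check_inside(self, config: SimulationConfig) -> None:
        h, w = config.image_shape
        cx, cy = self.center
        fw, fh = w * config.pixel_size, h * config.pixel_size
        if not (
            self.radius <= cx <= fw - self.radius
            and self.radius <= cy <= fh - self.radius
        ):
            raise GeometryError("colony disk is not fully inside the image frame")


def default_geometry(config: SimulationConfig) -> ColonyGeometry:
    """Colony geometry implied by the 1-D config: the colony is centered on
    the middle image row, at the configured distance from the deposit plane."""
    h, w = config.image_shape
    cx = config.colony_center_x - config.window_offset
    cy = 0.5 * h * config.pixel_size
    return ColonyGeometry(
        center=(cx, cy),
        radius=config.colony_radius,
        cell_seed=config.seed + 1,
        packing_fraction=1.0 - config.fill_fraction,
    )


@dataclass
class ImageStack:
    """Two-channel time-lapse stack.

    ``frames`` has shape (T, 2, H, W); channel 0 is the colony stain,
    channel 1 the diffusing solute.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    channel_names: tuple[str, str] = ("colony_stain", "solute")

    def __post_init__(self) -> None:
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (T, 2, H, W)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_index(self, t: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.timestamps) - t)))

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF (pages ordered frame-major, then channel)."""
        tifffile.imwrite(
            path,
            self.frames,
            photometric="minisblack",
            metadata={
                "axes": "TCYX",
                "pixel_size_um": self.pixel_size,
                "timestamps_s": [float(t) for t in self.timestamps],
                "channels": list(self.channel_names),
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        frames = frames.reshape((-1, 2) + frames.shape[-2:])
        ts = np.asarray(
            meta.get("timestamps_s", np.arange(frames.shape[0], dtype=float))
        )
        return cls(
            frames=frames,
            timestamps=ts,
            pixel_size=float(meta.get("pixel_size_um", 1.0)),
            channel_names=tuple(meta.get("channels", ("colony_stain", "solute"))),
        )


@dataclass
class GroundTruth:
    """Sidecar record of the quantities a recovery test must reproduce."""

    d_in: float
    d_out: float
    geometry: ColonyGeometry
    config: SimulationConfig

    @property
    def ratio_in_out(self) -> float:
        return self.d_in / self.d_out

    def to_json(self) -> str:
        return json.dumps(
            {
                "d_in_um2_per_s": self.d_in,
                "d_out_um2_per_s": self.d_out,
                "ratio_in_out": self.ratio_in_out,
                "geometry": {
                    "center_um": list(self.geometry.center),
                    "radius_um": self.geometry.radius,
                    "cell_seed": self.geometry.cell_seed,
                    "cell_radius_um": self.geometry.cell_radius,
                    "packing_fraction": self.geometry.packing_fraction,
                },
                "config": self.config.to_dict(),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        g = d["geometry"]
        return cls(
            d_in=d["d_in_um2_per_s"],
            d_out=d["d_out_um2_per_s"],
            geometry=ColonyGeometry(
                center=tuple(g["center_um"]),
                radius=g["radius_um"],
                cell_seed=g["cell_seed"],
                cell_radius=g["cell_radius_um"],
                packing_fraction=g["packing_fraction"],
            ),
            config=SimulationConfig.from_dict(d["config"]),
        )


def plane_source_profile(
    x: np.ndarray, t: float, mass: float, d: float
) -> np.ndarray:
    """Closed-form concentration from an instantaneous plane source at x = 0
    on a half-space with a reflecting surface.

    C(x, t) = M / sqrt(pi D t) * exp(-x^2 / (4 D t))

    which integrates to M over x >= 0.  The Gaussian argument -x^2/(4Dt) is
    what the linearized slope fit inverts; the prefactor only sets the
    intercept, so any constant amplitude convention leaves estimated D
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    return mass / np.sqrt(np.pi * d * t) * np.exp(-(x**2) / (4.0 * d * t))


def _face_diffusivity(config: SimulationConfig, x_centers: np.ndarray) -> np.ndarray:
    """Harmonic-mean diffusivity at the faces between grid cells.

    The harmonic mean preserves flux continuity across the step change in D
    at the colony boundary.
    """
    d = np.full_like(x_centers, config.d_out)
    if config.colony_radius > 0:
        inside = np.abs(x_centers - config.colony_center_x) < config.colony_radius
        d[inside] = config.d_in
    return 2.0 * d[:-1] * d[1:] / (d[:-1] + d[1:])


def solve_diffusion(config: SimulationConfig) -> ConcentrationField:
    """Solve the 1-D diffusion problem with an instantaneous plane source.

    Explicit forward-time central-space finite-volume scheme on a uniform
    grid, no-flux boundaries at both ends, all deposited mass placed in the
    first cell at t = 0.  The solver step is ``0.4 dx^2 / max(D)`` unless a
    (stability-checked) ``solver_dt`` is configured.

    Returns
    -------
    ConcentrationField
        Concentration at every configured frame time, on cell centers.
    """
    dx = config.grid_spacing
    n = int(round(config.domain_length / dx))
    x = (np.arange(n) + 0.5) * dx
    c = np.zeros(n)
    c[0] = config.deposit_mass / dx

    dmax = max(config.d_in, config.d_out)
    dt_max = (
        config.solver_dt
        if config.solver_dt is not None
        else STABILITY_FACTOR * dx * dx / dmax
    )
    d_face = _face_diffusivity(config, x)
    coef = d_face / (dx * dx)

    times = config.frame_times
    out = np.empty((len(times), n))
    t_now = 0.0
    for k, t_target in enumerate(times):
        span = t_target - t_now
        if span > 0:
            n_steps = max(1, int(np.ceil(span / dt_max)))
            dt = span / n_steps
            for _ in range(n_steps):
                g = coef * np.diff(c)  # flux divergence terms, length n-1
                c[0] += dt * g[0]
                c[-1] -= dt * g[-1]
                c[1:-1] += dt * (g[1:] - g[:-1])
            t_now = t_target
        out[k] = c
    return ConcentrationField(x_grid=x, t_grid=times, values=out)


def _hex_cell_centers(geometry: ColonyGeometry) -> np.ndarray:
    """Non-overlapping cell-disk centers filling the colony cross-section.

    Sites of a jittered hexagonal lattice whose spacing realizes the target
    packing fraction; jitter is bounded by half the inter-disk gap so disks
    can never overlap, and only sites whose disk lies fully inside the
    colony are kept (the lattice spacing is corrected for the excluded rim
    so the realized in-colony coverage still matches ``packing_fraction``).
    """
    r = geometry.cell_radius
    big_r = geometry.radius
    p = geometry.packing_fraction
    if p <= 0 or big_r <= r:
        return np.empty((0, 2))
    # correct target coverage for the rim of width r that holds no centers
    p_eff = min(0.88, p * big_r**2 / (big_r - r) ** 2)
    a = r * np.sqrt(2.0 * np.pi / (np.sqrt(3.0) * p_eff))
    jitter = 0.49 * max(a - 2.0 * r, 0.0)

    rng = np.random.default_rng(geometry.cell_seed)
    phase = rng.uniform(0.0, a, size=2)
    theta = rng.uniform(0.0, np.pi / 3.0)

    m = int(np.ceil(2.2 * big_r / a)) + 2
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    xs = (i + 0.5 * (j % 2)) * a + phase[0]
    ys = j * (np.sqrt(3.0) / 2.0 * a) + phase[1]
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    pts = pts @ rot.T
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    keep = np.hypot(pts[:, 0], pts[:, 1]) <= big_r - r
    cx, cy = geometry.center
    return pts[keep] + np.array([cx, cy])


def _cell_mask(geometry: ColonyGeometry, config: SimulationConfig) -> np.ndarray:
    """Boolean (H, W) mask of pixels covered by cell disks."""
    h, w = config.image_shape
    ps = config.pixel_size
    mask = np.zeros((h, w), dtype=bool)
    r_px = geometry.cell_radius / ps
    pad = int(np.ceil(r_px)) + 1
    for cx, cy in _hex_cell_centers(geometry):
        jc, ic = cx / ps, cy / ps  # column (x) and row (y) in px
        j0, j1 = int(jc) - pad, int(jc) + pad + 1
        i0, i1 = int(ic) - pad, int(ic) + pad + 1
        j0, i0 = max(j0, 0), max(i0, 0)
        j1, i1 = min(j1, w), min(i1, h)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1), indexing="xy")
        hit = (jj - jc) ** 2 + (ii - ic) ** 2 <= r_px**2
        mask[i0:i1, j0:j1] |= hit
    return mask


def render_stack(
    field: ConcentrationField,
    geometry: ColonyGeometry,
    config: SimulationConfig,
) -> tuple[ImageStack, GroundTruth]:
    """Render the solved field as a noisy two-channel image stack.

    Solute channel: ``background + gain * C(x) * f(x, y)`` where f is 1 in
    the matrix and 0 on non-fluorescent cell disks inside the colony; the
    gain maps the brightest rendered concentration to ~75% of the dynamic
    range.  Stain channel: bright disks at the cell positions.  Both
    channels receive multiplicative Gaussian noise of scale ``noise_sigma``
    before clipping and quantization to ``bit_depth``.
    """
    h, w = config.image_shape
    ps = config.pixel_size
    geometry.check_inside(config)

    x_pix = config.window_offset + np.arange(w) * ps
    if x_pix[0] < 0 or x_pix[-1] > field.x_grid[-1] + 0.5 * config.grid_spacing:
        raise GeometryError(
            f"imaging window [{x_pix[0]:.1f}, {x_pix[-1]:.1f}] um lies outside "
            f"the solved domain [0, {field.x_grid[-1]:.1f}] um"
        )

    cells = _cell_mask(geometry, config)
    fluor_fraction = np.where(cells, 0.0, 1.0)

    vmax = float(2**config.bit_depth - 1)
    c_window = np.interp(x_pix, field.x_grid, field.values[0])
    c_peak = max(float(c_window.max()), 1e-300)
    for row in field.values[1:]:
        c_peak = max(c_peak, float(np.interp(x_pix, field.x_grid, row).max()))
    gain = (0.75 * vmax - config.background_level) / c_peak if c_peak > 0 else 0.0
    gain = max(gain, 0.0)

    sigma_px = config.psf_sigma / ps
    stain_clean = np.full((h, w), config.background_level)
    stain_clean[cells] = 0.85 * vmax
    stain_clean = _blur(stain_clean, sigma_px)

    rng = np.random.default_rng(config.seed)
    frames = np.empty((len(field.t_grid), 2, h, w), dtype=_dtype_for(config.bit_depth))
    for k in range(len(field.t_grid)):
        c_row = np.interp(x_pix, field.x_grid, field.values[k])
        solute_clean = _blur(
            config.background_level + gain * c_row[None, :] * fluor_fraction, sigma_px
        )
        for ch, clean in ((0, stain_clean), (1, solute_clean)):
            noisy = clean * (1.0 + config.noise_sigma * rng.standard_normal((h, w)))
            frames[k, ch] = np.clip(np.rint(noisy), 0, vmax)

    stack = ImageStack(
        frames=frames, timestamps=np.asarray(field.t_grid), pixel_size=ps
    )
    truth = GroundTruth(
        d_in=config.d_in, d_out=config.d_out, geometry=geometry, config=config
    )
    return stack, truth


def _dtype_for(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth <= 8 else np.uint16)


def _blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian optical blur; mean-preserving, so the in-colony
    fluorescent-volume fraction is unchanged."""
    if sigma_px <= 0:
        return image
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(image, sigma_px, mode="nearest")


def _dextran_like(d_in: float, d_out: float, radius: float = 16.0) -> dict:
    return {"d_in": d_in, "d_out": d_out, "colony_radius": radius}


#: Documented fixture presets.  The dextran presets reproduce the study
#: conditions for rhodamine-labeled dextrans diffusing past Lactococcus
#: lactis colonies in model cheese: d_in from the reported free-water /
#: in-colony ratio at the solute's hydrodynamic radius, d_out from the
#: reported in/out ratio, colony diameters in the observed 30-40 um range.
SCENARIOS: dict[str, dict] = {
    "dextran10-LD61-like": _dextran_like(2.17, 4.01),
    "dextran70-LD61-like": _dextran_like(1.79, 3.57),
    "dextran155-LD61-like": _dextran_like(0.79, 1.97),
    "dextran10-TIL1230-like": _dextran_like(1.86, 3.58, 17.5),
    "dextran70-TIL1230-like": _dextran_like(1.12, 2.79, 17.5),
    "dextran155-TIL1230-like": _dextran_like(0.59, 1.73, 17.5),
    # recovery scenarios with round-number ground truth
    "ratio-recovery-0.4": _dextran_like(1.6, 4.0),
    "ratio-recovery-0.5": _dextran_like(2.0, 4.0),
    # controls
    "uniform-D4": {"d_in": 4.0, "d_out": 4.0, "colony_radius": 16.0,
                   "fill_fraction": 1.0},
    "exclusion-only": {"d_in": 4.0, "d_out": 4.0, "colony_radius": 16.0},
}


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def scenario_config(scenario_name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """SimulationConfig for a named preset (see :data:`SCENARIOS`)."""
    try:
        params = dict(SCENARIOS[scenario_name])
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {scenario_name!r}; choose one of {list_scenarios()}"
        ) from None
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


def simulate_scenario(
    scenario_name: str, seed: int = 0, **overrides
) -> tuple[ImageStack, GroundTruth]:
    """Run a preset end to end: solve the field and render the stack."""
    config = scenario_config(scenario_name, seed=seed, **overrides)
    field = solve_diffusion(config)
    return render_stack(field, default_geometry(config), config)


def make_fixture(
    scenario_name: str, seed: int, out_dir: str | Path = ".", **overrides
) -> tuple[Path, Path]:
    """Write a preset scenario to disk: multi-page TIFF + ground-truth JSON.

    Rerunning with the same (scenario, seed) produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate_scenario(scenario_name, seed=seed, **overrides)
    stem = f"{scenario_name}_seed{seed}"
    tiff_path = out_dir / f"{stem}.tif"
    truth_path = out_dir / f"{stem}_truth.json"
    stack.save(tiff_path)
    truth_path.write_text(truth.to_json())
    return tiff_path, truth_path


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
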