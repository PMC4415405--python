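# Methods

## Physical model

A fluorescent solute is deposited at time zero on the surface of a gel as
an instantaneous plane source of surface concentration M and diffuses along
the axis x perpendicular to that surface. For a homogeneous medium the
short-time solution is Gaussian,

    C(x, t) = M / √(π D t) · exp(−x² / (4 D t)),

where the prefactor is fixed by mass conservation on the half-space with a
reflecting surface (∫₀^∞ C dx = M). Prefactor conventions differ across
texts; the estimator is insensitive to them because only the exponent is
used: ln C is linear in x² with slope −1/(4Dt), so

    D = −1 / (4 · t · slope)

recovered by ordinary least squares on (x², ln I) over a spatial window.
Fluorescence intensity I is assumed proportional to concentration; any
multiplicative gain — detector gain, labeling efficiency, or the in-colony
fluorescent-volume fill factor — moves only the intercept, never the slope.
This is why D_in can be fitted on raw in-colony intensities even though
roughly half the colony volume is occupied by non-fluorescent cells.

A colony occupying [x_c − R, x_c + R] carries a distinct effective
diffusivity d_in; the surrounding matrix has d_out. Physics is strictly
one-dimensional (a plane front); the colony enters the solver as a slab.

## Numerical scheme

Explicit forward-time central-space finite-volume discretization on a
uniform grid (default Δx = 1 μm over 800 μm), no-flux boundaries, all
deposited mass in the first cell at t = 0. Interface diffusivities are the
harmonic mean of the adjacent cell values, which preserves flux continuity
across the colony boundary. The solver step is 0.4·Δx²/max(D) (stability
limit 0.5); a user-supplied step is validated against that bound. The
discrete mass dx·ΣC is conserved to round-off; the `mass()` diagnostic
integrates trapezoidally on the grid extended to the domain boundaries with
zero-gradient edge values, which makes the quadrature exact for the
finite-volume solution. Against the closed-form Gaussian, a homogeneous run
at 30 min agrees to ≤ 0.6% max relative error wherever C exceeds 10⁻⁶ of
its peak.

## Rendering and what the synthetic data does (and does not) emulate

Frames are 512×512 px at 0.62 μm/px (a plausible field of view for a 40×
objective), acquired every 5 min from 10 min to 150 min after the deposit.
The imaged window starts `window_offset` (default 40 μm) from the deposit
plane. Solute-channel intensity is background + gain·C(x)·f(x,y), where f
is 1 in the matrix and 0 on cell disks; the gain maps the brightest
concentration in the stack to ~75% of the 8-bit range. The stain channel
shows the same cell disks bright. Both channels are blurred with a Gaussian
point-spread function (σ = 0.5 μm) — confocal optics never deliver
hard-edged 1-μm objects — then multiplied by (1 + σ_noise·ε), ε ~ N(0,1),
σ_noise = 0.05, clipped and quantized to 8 bits. With these defaults the
matrix-region fit achieves R² ≈ 0.99 and the in-colony fit R² ≈ 0.7: the
dominant in-colony "noise" is cell speckle, not the detector.

Cells are hard disks of radius 0.5 μm (coccus-scale). Placement uses a
seeded, jittered hexagonal lattice whose spacing realizes the target
packing fraction (default 0.5): jitter is bounded by half the inter-disk
gap, so overlap is impossible by construction, and the spacing is corrected
for the cell-free rim so the realized in-colony coverage matches the
target. Random sequential adsorption was rejected because packing 0.5 is
too close to its jamming limit (~0.547) to reach reliably. A rendered
uniform-concentration colony at fill 0.5 shows an in/out intensity ratio of
0.50 ± 0.02.

Not emulated: 3-D confocal sectioning (the 2-D render uses the sphere's
equatorial cross-section), photobleaching, stage drift, bacterial growth
during acquisition, and — most importantly — lateral transport around the
colony. Real colonies are spheres that solutes can bypass; the 1-D slab
maximizes the colony's obstruction. Passing recovery tests therefore
validate the estimator against the stated 1-D forward model, not against
every feature of real stacks.

## Estimation pipeline choices

- **Colony localization**: Otsu threshold on the stain channel, closing
  (disk radius 3 px) to merge individual stained cells, hole filling,
  largest connected component above a 10 μm minimum equivalent diameter
  (ties broken by area), Kasa least-squares circle fit to the component
  boundary. A robust contrast guard (component mean must exceed the frame
  median by 10 median-absolute-deviations) rejects blank or noise-only
  frames. Over 20 seeded fixtures: median center error 0.13 px, median
  radius error 3.5%.
- **Profiles**: the axial line is horizontal through the colony center,
  512 samples, width-10 mean via bilinear sampling perpendicular to the
  line. Positions are micrometers from the source-side image edge.
- **Origin**: fits convert positions to distance from the deposit plane by
  adding the window offset. An origin error adds a linear-in-x term that
  the x² regression absorbs as bias, so the offset must come from the
  acquisition geometry (the ground-truth sidecar, for synthetic stacks).
- **Background**: the configured background level (for real data, a robust
  low percentile of the first frame) is subtracted before taking logs and
  before normalization; a raw offset would curve ln I vs x².
- **Fit regions**: interior window is the colony span minus a 3-px rim
  buffer. The outside fit defaults to the **upstream** (source-side) matrix
  window. In a 1-D medium the colony transmits reduced flux, so the
  downstream segment sits on a lower intensity branch: pooling upstream and
  downstream segments into one regression tilts the slope steep and was
  measured to bias D_out low by ~11% on synthetic stacks. The upstream
  window shares its local flux perturbation with the colony interior, so
  the residual biases largely cancel in the D_in/D_out ratio (median
  recovery error 1–3% at ratios 0.4–0.55). `outside_mode` exposes
  "pooled" and "downstream" alternatives.
- **Fit time**: 1800 s by default — early enough that the Gaussian
  short-time solution holds, late enough that the front spans the colony.
  Points with non-positive background-subtracted intensity are dropped and
  counted; fewer than 5 usable points raises an error; a non-negative
  slope flags the fit and reports D as undefined rather than raising.
- **Relative profiles**: upstream window of 20 px adjacent to the colony
  entry, separated by a 3-px buffer; values are not stated in the source
  protocols and were chosen to keep the window inside the field while
  avoiding partial-volume rim pixels.

## Scenario presets

The dextran presets encode the study conditions for 10/70/155 kDa
rhodamine-labeled dextrans around *L. lactis* LD61 and TIL1230 colonies:
d_in is the Stokes–Einstein free-water value at the solute's hydrodynamic
radius divided by the reported D_w/D_in ratio, and d_out follows from the
reported D_in/D_out ratio (e.g. dextran10-LD61-like: d_in = 2.17,
d_out = 4.01 μm²/s). Colony diameters are 32–35 μm, in the observed
30–40 μm range. `ratio-recovery-0.4/0.5` provide round-number ground truth
for recovery tests; `uniform-D4` and `exclusion-only` are controls
(no diffusivity contrast, with and without cell exclusion). Solute presets
follow the tabulated molecular weights (10/70/155 kDa).

## Derived quantities and statistics

D_w uses k_B = 1.380649×10⁻²³ J/K, T = 293.15 K, η = 1.002 mPa·s (water at
20 °C, the reference condition for the tabulated free-water values, even
though the diffusion experiments run at 19 °C; constants are overridable).
The tortuosity index is √(D_w/D_in); report output rounds ratios to 2
decimals and indices to 1, and index² equals the unrounded ratio to 10⁻¹².
The MATS percentage is 100·(OD_initial − OD_after)/OD_initial; negative
values are reported, not raised. ANOVA uses the classical sums-of-squares
decomposition with p from the F distribution; degenerate inputs (zero
within-group variance) are flagged, not raised. Tukey HSD draws critical
values from scipy's studentized-range distribution; unbalanced designs use
the harmonic-mean group size (Tukey–Kramer). Exact p-values are always
reported; significance thresholds are configuration, not hard-coded
conclusions.

## Problem sizes

Tests and the acceptance script use 20-seed ensembles of full 512×512,
29-frame stacks; the 1-D field is seed-independent and solved once per
scenario, with only rendering, localization and fitting repeated per seed.
The whole suite runs in under two minutes on one core.

## Known limitations

- The estimator inherits the instantaneous-source assumption. When the
  deposit instead acts as a sustained reservoir, the erfc (constant-source)
  solution applies; it is not implemented, and fits to such data would be
  biased.
- In-colony estimates are intrinsically noisy (≈45 fit points, speckle-
  dominated): single-stack D_in values scatter by ~20%; replicate medians
  are required for quantitative ratios.
- The 1-D slab colony overstates upstream pile-up and downstream shadowing
  relative to a real sphere; absolute D_out from the pooled or downstream
  windows is biased at the several-percent level by construction.
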