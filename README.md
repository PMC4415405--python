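# colonydiff

Quantify how fast solutes diffuse **inside** bacterial colonies versus the
matrix **around** them, from two-channel time-lapse confocal image stacks.

When bacteria such as *Lactococcus lactis* are immobilized in a dense food
matrix (a renneted skim-milk "model cheese"), they grow as near-spherical
colonies 30–40 μm across. Whether nutrients reach the cells at the center of
a colony — and whether metabolites get out — is a transport question: what is
the effective diffusion coefficient of a solute in the colony interior
(D_in) compared to the surrounding matrix (D_out) and to free water (D_w)?

`colonydiff` implements the full measurement chain for the classic
plane-front experiment, plus a forward simulator so every stage can be
verified against known ground truth:

- **simulate** — solves 1-D diffusion of an instantaneous plane source
  through a medium containing a colony with distinct diffusivity
  (explicit finite-volume scheme, harmonic-mean interface diffusivities),
  and renders two-channel noisy image stacks (stain + solute) in which the
  colony interior holds non-fluorescent cell disks.
- **profiles** — locates the colony in the stain channel (Otsu threshold,
  connected components, circle fit) and extracts the standard 512-px-long,
  10-px-wide axial line profile per frame, plus relative-intensity profiles
  normalized by the upstream window.
- **fitdiff** — the estimator: for a plane instantaneous source,
  C(x,t) ∝ exp(−x²/4Dt), so ln C is linear in x² with slope −1/(4Dt).
  Ordinary least squares on (x², ln I) per region gives
  **D = −1/(4·t·slope)**, separately inside and outside the colony.
- **physchem** — Stokes–Einstein free-water diffusivities
  D_w = k_B·T/(6πη·r_h), ratio tables, tortuosity index √(D_w/D_in), and
  MATS adhesion percentages for cell-surface characterization.
- **stats_report** — one-way ANOVA, Tukey HSD at the 95% level, and the
  regression of D_eff against hydrodynamic radius.

## Worked example

Simulate a 10 kDa-dextran-like experiment, extract profiles, and fit:

```sh
colonydiff simulate --scenario dextran10-LD61-like --seed 1 --out .
colonydiff profile --stack dextran10-LD61-like_seed1.tif --out profiles.csv
colonydiff fit --profiles profiles.csv --mask profiles.mask.json \
    --time 1800 --background 5 --x-offset 40 --out fits.csv
```

which prints (seed 1):

```
 region  slope_per_um2  intercept  d_eff_um2_per_s       r2  n_points  n_dropped  fit_time_s  flagged
 inside      -0.000052   4.728639         2.655397 0.721941        44          0      1800.0    False
outside      -0.000032   4.835109         4.390846 0.996557       227          0      1800.0    False
D_in/D_out ratio: 0.605
```

The fit is taken 30 min (1800 s) after the deposit. The outside fit is
nearly perfectly linear (R² ≈ 0.997); the in-colony fit is noisier
(R² ≈ 0.72) because the non-fluorescent cells speckle the signal. A single
seed scatters around the configured truth (D_in/D_out = 0.54 here); the
median over 20 seeds recovers it to within a few percent.

Derived quantities from tagged fits:

```sh
colonydiff report --fits tagged.csv --out table.csv
```

```
   solute strain  d_in  d_out       d_w  ratio_in_out  ratio_w_in  tortuosity
dextran10   LD61  2.17   4.01 93.170087          0.54       42.94         6.6
dextran70   LD61  1.79   3.57 35.715200          0.50       19.95         4.5
```

D_w is the Stokes–Einstein free-water value at 20 °C; `tortuosity` is
√(D_w/D_in), an index of how convoluted the interstitial path between cells
is (1 = free diffusion).

The same operations are available as library functions
(`simulate_scenario`, `locate_colony`, `extract_profile`,
`estimate_din_dout`, `build_table3`, `one_way_anova`, ...).

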