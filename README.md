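# tirfex

Detection and spatial analysis of single-vesicle exocytosis in TIRF
microscopy movies, built for experiments that visualize receptor traffic
with pH-sensitive (pHluorin) or quenchable (HaloTag ligand) ecto-tags —
for example β1 integrin delivery to focal adhesions.

`tirfex` is a Python library with a thin command-line front end. It is
aimed at cell biologists and image analysts who need to

- detect **exocytic fusion events** in a post-photobleach TIRFM movie and
  separate them from docked vesicles and moving endosomes,
- measure each event's **distance to the nearest focal adhesion (FA)** and
  test spatial targeting against a **Monte Carlo complete-spatial-randomness
  (CSR)** null,
- quantify **endocytosis** from surface-quench intensity traces and
  **recycling** from dual-label FA intensity ratios,

and who want every step testable against synthetic movies with known
ground truth (the package ships its own generator).

## The method

A fusion event carries a two-part optical signature. When a cargo-loaded
vesicle fuses, the reporter de-acidifies and the spot intensity jumps;
the released cargo then diffuses laterally in the plasma membrane, so the
spot's width grows while its integrated intensity is conserved. For an
isotropic Gaussian spot of width σ,

- FWHM = 2√(2 ln 2) · σ,
- free diffusion predicts σ²(t) = σ₀² + 2D·(t − t₀) after fusion at t₀.

Candidates are local maxima of the spatially smoothed frame minus a
rolling temporal-median baseline, thresholded at 5 robust noise SDs
(scaled MAD) with a next-frame persistence check. Each candidate is
fitted per frame with a 2D Gaussian + offset; it is accepted as fusion
iff it (1) rises above its pre-event level, (2) spreads — the
inverse-variance-weighted FWHM-vs-time slope is positive with p < 0.05 —
and (3) stays put (trajectory drift ≤ 2 px), otherwise it is rejected as
`no_rise`, `no_spread`, `moving` or `fit_failure`.

Spatial targeting is tested per cell: the distance from each accepted
event to the nearest FA pixel (Euclidean distance transform of the FA
mask, subpixel-interpolated) is compared with 100 placements of the same
number of events uniformly inside the cell footprint; per-cell observed
medians vs simulated mean medians are compared across cells with a
two-sample Student's t-test.

## Worked example

```bash
python examples/02_fa_proximity_csr.py
```

```
observed median distance to nearest FA: 0.213 um (19 of 60 events inside an FA)
CSR null: mean of 100 per-rep medians = 4.909 um
cumulative frequency at [0.25 0.5  1.   2.  ] um:
  observed  [0.63 0.87 1.   1.  ]
  simulated [0.01 0.03 0.06 0.14]
```

Sixty FA-directed events sit a median 0.21 µm from the nearest adhesion,
while the same number of events scattered at random in the same cell
footprint sit ~4.9 µm away — the cumulative-frequency curves barely
overlap, i.e. strong spatial targeting. The other examples cover
detection (`01`), quench-based endocytosis (`03`) and the dual-label
recycling ratio plus activation index (`04`).

The full pipeline runs from the shell and writes masks, event tables,
distance tables, CSR simulations and a `summary.json`:

```bash
tirfex simulate --out out/ --seed 1            # synthetic cells end to end
tirfex analyze --movie movie.tif --cell mask.tif --out out/
tirfex report --out out/                       # regenerate plots
```

## Layout

- `src/tirfex/synth.py` — synthetic movie/mask/trace generator (ground truth)
- `src/tirfex/segmentation.py` — FA and cell-footprint masks
- `src/tirfex/detection.py` — candidates, Gaussian fits, fusion classifier, alignment
- `src/tirfex/spatial.py` — nearest-FA distances, CSR null, median comparison
- `src/tirfex/pools.py` — quench fraction, FA ratio timecourse, activation index
- `src/tirfex/pipeline.py`, `cli.py` — orchestration and the `tirfex` command
- `src/tirfex/scenarios.py` — self-contained benchmark scenarios
- `docs/methods.md` — model assumptions, parameters, numerical choices
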