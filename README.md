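# ecmquant

Quantification of microbial aggregation and biofilm/EPS structure from
calibrated microscopy. The package targets researchers studying
algal–bacterial interactions and extracellular-matrix (ECM) formation
who need two measurements that standard image-analysis GUIs only
provide interactively:

1. **Aggregate-size classification (2-D).** Given binary segmentations
   of phase-contrast fields, how many imaged particles are sub-cellular
   debris, single cells, or multi-cell aggregates — and how large are
   the aggregates relative to a single cell?
2. **Biovolume quantification (3-D).** Given two-channel confocal
   z-stacks (a cell stain and a lectin-labelled exopolysaccharide
   (EPS) channel), how much EPS biovolume exists per unit cell
   biovolume, and how thick is the biofilm?

A synthetic-scene generator produces ground-truthed inputs for both
chains, so every step of the pipeline is testable without microscope
data.

## Methods at a glance

**Aggregate classification.** Connected components (8-connectivity) of
a calibrated mask are measured in µm²; particles < 1 µm² or touching
the image border are excluded. The sorted log₁₀ areas form a rank
curve with three regimes — a concave debris limb, a flat single-cell
plateau, and a convex aggregate tail. The two regime boundaries
(i₁, i₂) are found by *exact* minimization of the summed per-segment
OLS residuals over all admissible boundary pairs. With median *m* and
raw median absolute deviation (MAD) of the middle segment, a particle
with log₁₀ area *x* is classified

    aggregate  iff  x > m + 3·MAD
    debris     iff  x < m − 3·MAD
    single     otherwise.

The aggregate percentage counts aggregates among cells + aggregates,
and each aggregate size is normalized by the mean single-cell area
(µm², linear scale) of its own image.

**Biovolume quantification.** Each channel is optionally denoised
(uniform kernel, default 5×5×3 in x, y, z) and background-subtracted
(white top-hat, cubic element), then segmented by 3-class Otsu
thresholding on channel-max–normalized intensity: only the top class
is foreground, and a per-channel relative floor applies (defaults
0.085 for the EPS/FITC channel, 0.07 for the cell channel). The stack
is dissected into cubes (default side 20 voxels) and the EPS/cell
biovolume ratio is

    ratio = Σ shape_biovolume·(rel_EPS − rel_overlap)
          / Σ shape_biovolume·rel_cell

which reduces to (V_EPS − V_overlap)/V_cell. Dim cubes can be removed
by a raw mean-intensity floor (strict >, default 75 A.U.). Thickness
metrics: per-(y,x)-column local thickness = (top foreground z-index
+ 1)·z-pitch, and its mean over covered columns.

## Worked example

```sh
python analysis/01_simulate_scenes.py
python analysis/02_classify_aggregates.py
python analysis/03_quantify_biovolume.py
python analysis/04_compare_distributions.py
```

prints (abridged):

```
design_10pct: designed 10%, recovered 10.07% (60 aggregates / 536 singles / 164 debris)
design_20pct: designed 20%, recovered 20.17% (120 aggregates / 475 singles / 165 debris)
design_30pct: designed 30%, recovered 30.69% (182 aggregates / 411 singles / 167 debris)
EPS/cell ratio: 0.6352 (truth-derived expectation 0.6400)
mean thickness: 2.837 µm, coverage 0.97
design_20pct vs design_30pct: D = 0.0708, p = 0.862 (n = 120, 182)
```

Reading: across six simulated fields the classifier recovers the
designed aggregate percentages to well under one percentage point; the
3-D chain recovers the designed EPS/cell biovolume ratio (0.8 with a
0.2 overlap fraction gives an expected net ratio 0.64) to < 1 %; and
the Kolmogorov–Smirnov comparison correctly finds no difference
between relative-size distributions generated from the same
aggregate-size model.

The same stages are available as a CLI (`ecmquant simulate`,
`ecmquant classify-aggregates`, `ecmquant quantify-biovolume`,
`ecmquant thickness`, `ecmquant compare`); every stage writes a JSON
run report with a config hash and input checksums, and re-running with
the same config and seed reproduces byte-identical outputs.

## Layout

- `src/ecmquant/` — the library: `synthetic` (scene generators),
  `aggregates` + `changepoint` (2-D chain), `biovolume` (3-D chain),
  `measures` (ECDF/KS/assay arithmetic), `config`, `imgio`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — model, parameter and design documentation.
- `tests/` — unit, property and end-to-end recovery tests.
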