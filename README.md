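# clonedyn

Genetically identical epithelial cells plated at clonal density grow into
strikingly different colonies: a minority of clones expand exponentially
while most slow down or stop as their cells become non-proliferative.
`clonedyn` is a Python toolkit for quantifying this clonal growth
heterogeneity — simulating it, inferring its parameters from clone-size
distributions, and testing whether the growth phenotype is heritable
through cell division using lineage barcodes.

It is aimed at quantitative cell biologists and modellers working with
clonal imaging data (cells per colony at fixed time points) and
lineage-barcode sequencing data (reads per barcode per sample).

## The model

Each clone starts from one proliferative cell. Proliferative cells **X**
divide or irreversibly arrest into non-proliferative cells **Y**:

```
X → 2X   at rate g_x  (divisions / cell / day)
X → Y    at rate k_y  (arrests  / cell / day)
```

Death and re-entry from **Y** are neglected. The stochastic model is
simulated exactly with Gillespie's algorithm; its mean-field counterpart
is the ODE system *dX/dt = (g_x − k_y)X*, *dY/dt = k_y X*, optionally with
a logistic division rate *g_x(1 − N/K)* that saturates at a carrying
capacity *K* (N = X + Y). Clone size is reported as total cells X + Y,
usually on the log2 scale ("number of cell divisions").

On top of the model the package provides:

- **Distribution-matching inference** (`KSParameterSweep`): sweep a
  (g_x, k_y) grid, simulate a clone ensemble per grid point, and score it
  against the observed clone-size distribution with the two-sample
  Kolmogorov–Smirnov test; the best fit minimises the KS statistic.
- **Growth-curve fitting** (`GrowthCurveModel`): multi-start least-squares
  fits of the exponential and logistic-rate ODEs to mean growth curves.
- **Modality analysis** (`bimodality_coefficient`, `GmmModalityModel`):
  Sarle's bimodality coefficient, *b = (s² + 1) / (k_e + 3(n−1)²/((n−2)(n−3)))*,
  with the 5/9 (bimodal) and 1/3 (unimodal) thresholds, plus a
  BIC-selected Gaussian mixture.
- **Heritability analysis** (`simulate_split_experiment`,
  `null_distribution`): barcoded founders expand through four doublings,
  split binomially into two samples, and grow; heritability is read out as
  top-decile overlap and per-barcode Pearson correlation against simulated
  non-heritable nulls (unimodal / bimodal-KDE / stochastic growth-rate
  draws).
- **Clone metrics** (`classify_proliferative`, `calibrate_spikeins`):
  top-10% proliferative classification and spike-in (50/500/1000 cells)
  reads-to-cells calibration.
- **Synthetic data** (`SyntheticConfig`, `gen_clone_size_table`, …):
  study-shaped clone tables, barcode split experiments and density series
  with known ground truth.

Fit-shaped components follow the scikit-learn estimator convention
(`fit`, `predict`/`transform`, trailing-underscore attributes) and compose
with sklearn pipelines; every estimator also has a plain functional
wrapper.

## Worked example

```python
import numpy as np
from clonedyn import (SyntheticConfig, gen_clone_size_table, log2_divisions,
                      classify_proliferative, bimodality_coefficient,
                      parameter_sweep)
from clonedyn.metrics import HIGH

cfg = SyntheticConfig(seed=7, days=(8.0,))          # 500 clones, day 8
table = gen_clone_size_table(cfg)
sizes = table["n_cells"].to_numpy()

div = log2_divisions(sizes[sizes > 1])              # one-cell clones filtered
call = bimodality_coefficient(div)
labels = classify_proliferative(sizes)              # top decile by size
hp, lp = sizes[labels == HIGH], sizes[labels != HIGH]

res_hp = parameter_sweep(hp, n_sim_clones=500, t_obs=8.0, seed=1)
res_lp = parameter_sweep(lp, n_sim_clones=500, t_obs=8.0, seed=1)
```

This prints (via the obvious `print` statements):

```
clones: 500  size range: 1 - 2718
bimodality coefficient (day 8): 0.395 -> ambiguous
top decile: 50 clones, median 338 cells; rest median 15 cells
sweep best fit, highly proliferative: g=0.80, k=0.00
sweep best fit, less proliferative:   g=0.75, k=0.40
```

Reading the output: the synthetic day-8 plate spans single cells to
~2,700-cell colonies; the division-count distribution sits between the
unimodal (1/3) and bimodal (5/9) thresholds; the largest 10% of clones are
~20-fold bigger than the rest. The KS sweep assigns the top decile a zero
arrest rate (pure exponential growth) and the remaining clones a high
arrest rate — note the top-decile cut selects the luckiest exponential
clones, so its fitted g exceeds the generating value (0.75) slightly,
while the less-proliferative fit compensates the lost large clones with a
higher g and k along the ridge of near-equivalent (g, k) fits.

The same stages are available from the shell:

```sh
clonedyn synth clones --seed 7 --out-dir out/
clonedyn sweep --in out/clones.tsv --day 8 --n-sim 500 --seed 1 --out out/sweep.tsv
clonedyn run --seed 7 --out-dir out/full   # metrics + modality + sweep + ODE + heritability
```

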