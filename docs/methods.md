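# Methods

This note documents the models, the numerical choices and the synthetic
data behind `clonedyn`, and what the test suite does and does not
establish about real data.

## The two-state clone growth model

A clone is founded by one proliferative cell. Two first-order reactions
compete, with mass-action propensities:

| reaction | stoichiometry | propensity |
|---|---|---|
| division | X → 2X | g_x · x |
| arrest | X → Y | k_y · x |

with x the current proliferative count. Assumptions: arrest is
irreversible, death is negligible, cells are exchangeable (no cell-cycle
phase structure, no spatial interactions). Time is in days, rates per
day. With a carrying capacity K the division propensity carries the
logistic factor max(0, 1 − (x + y)/K); the factor multiplies **division
only** — arrest is a cell-intrinsic fate change and has no obvious
crowding dependence, whereas division is what contact inhibition stops.
This choice is configurable in the sense that K may simply be omitted.

Simulation is Gillespie's direct method: exponential waiting times at the
total propensity, reaction chosen proportionally. `simulate_clone`
records every event; `simulate_ensemble` runs a numba-compiled
final-state kernel, one independent RNG substream per clone spawned from
the master seed (so results do not depend on ensemble size ordering and
are bit-reproducible). A hard cap (default 10^6 cells) guards runaway
supercritical runs; hitting it terminates the clone as if the horizon had
been reached and emits a warning in the trajectory path.

Downstream clone size is total cells x + y: fixed-plate nuclear counts
cannot distinguish proliferative from arrested cells, so the observable
is the total. The per-compartment counts are retained on every ensemble
for analyses that need them (e.g. extinction fractions).

Useful exact results used as test oracles: for k = 0 the process is a
Yule process, X(t) ~ Geometric(p = e^{−gt}) with mean e^{gt}; for
k < g the proliferative lineage goes extinct with probability k/g; for
k > g extinction is certain.

## Distribution-matching parameter inference

The (g_x, k_y) plane is swept on a grid (default 0–1 in 0.05 steps,
matching the resolution at which the rates are scientifically
distinguishable here); each grid point simulates `n_sim_clones` clones
(default 500, a typical per-replicate clone count) to the observation
day and is scored against the observed sizes with the two-sample
Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`, asymptotic p-values) on
log2 sizes. The KS statistic is invariant under the monotone log2
transform; the transform is kept because division counts are the
conventional axis. Each grid point uses its own derived substream; a
common-random-numbers mode reuses one substream everywhere, trading
independence for a smoother surface.

The best fit is the grid point with the smallest statistic; ties are
broken by largest p-value, then smallest k_y, then smallest g_x. The
tie-break matters because the KS surface has a ridge of near-equivalent
fits along directions that preserve the net rate g − k, which is why
fitted arrest rates are best reported as ranges.

The observed-sample loader applies the one-cell filter (imaging
convention) while simulated ensembles retain size-1 clones; the
asymmetry mirrors how the data are produced (a single fixed cell is not
scored as a clone, but the simulator must keep absorbed singletons to
get the distribution right) and both behaviours sit behind flags.

## Growth-curve ODE fitting

Mean-field models: exponential (dX/dt = (g−k)X, dY/dt = kX; closed form
used directly) and logistic-rate (dX/dt = gX(1 − N/K) − kX, dY/dt = kX,
N = X + Y; integrated with LSODA at rtol 1e-8 inside the cost, 1e-9 for
reported solutions). The degenerate g = k case uses the limiting closed
form (constant X, linear Y), never a division by g − k.

The cost is the sum of squared differences between the model total and
the observed curve; a log1p-scale option weights decades equally, which
matters because clone sizes span orders of magnitude. Optimisation is
L-BFGS-B under bounds (rates in [0, 2]/day, K in [2, 10^4] cells) with
multi-start (default 10 starts: the initial guess plus uniform draws,
seeded). The reported cost is never worse than the cost at the initial
guess, and an abnormal line-search termination at an exact optimum is
accepted as converged only if a refit from the returned point cannot
improve it.

**Identifiability caveat:** from a total-cells curve alone, k enters the
exponential model only through the small additive offset k/(g−k), so
when k ≪ g it is weakly identified under noise; recovery to ~10% at 5%
signal noise holds in the arrest-dominated regime (k comparable to g)
with the log-scale cost, and the test suite pins exactly that regime.
Doubling time is reported as ln 2 / (g_x − k_y), the net-rate
definition; quoted doubling times should always be checked against the
net rate they imply.

## Modality analysis

Sarle's bimodality coefficient with the finite-sample correction,
b = (s² + 1) / (k_e + 3(n−1)²/((n−2)(n−3))), using bias-corrected sample
skewness and excess kurtosis (the correction term presumes them).
Thresholds: b > 5/9 bimodal (5/9 is the asymptotic uniform value),
b < 1/3 unimodal (the Gaussian value), otherwise ambiguous. The
coefficient is affine-invariant and lies in (0, 1]. It is a moment-based
screen: heavy skew alone can push it above 5/9, which is why it is
paired with a mixture model.

The Gaussian mixture is scikit-learn's `GaussianMixture` (EM, tol 1e-6,
500 iterations max, 5 seeded k-means restarts), with the component count
chosen by BIC (for 1-D full covariance, 3k − 1 free parameters).
Modality is assessed on log2 sizes, consistent with the division-count
axis used everywhere else; raw sizes are so right-skewed that any
mixture on them is dominated by the tail.

## Heritability analysis

The split experiment: every barcode expands deterministically to
2^pre_doublings copies (default 4 → 16 copies, enough that both samples
see every barcode), the copies are split Binomial(copies, 1/2), and each
barcode-in-sample grows to round(initial · 2^r) cells, with the division
count r drawn once per barcode (heritable) or independently per sample
(non-heritable). An `exact_split` option removes the binomial noise; it
is the only setting under which a heritable noiseless experiment gives a
correlation of exactly 1, since the split itself decorrelates samples
slightly.

Readouts: (i) the fraction of top-decile barcodes shared, with the
per-sample denominator |A∩B|/|A| (equal-size top sets, ties broken by
barcode id; |A∩B|/|A∪B| available); under no heritability the expected
overlap is the decile fraction, 0.10. (ii) Pearson correlation of
per-barcode abundances. Both statistics are invariant under per-sample
linear rescaling, so reads, reads-per-million and calibrated cell
numbers give identical r and overlap as long as the calibration is
linear; calibrated cells are still the recommended reporting scale.

Non-heritable nulls redraw r from a reference division-count sample
(observed day-8 log2 sizes or the synthetic stand-in) in one of three
ways: **unimodal** — Gaussian with moment-matched μ, σ; **bimodal** —
smoothed bootstrap of the reference (resample + Gaussian jitter at the
Scott KDE bandwidth, the standard sampler for a Gaussian KDE);
**stochastic** — uniform resampling of the reference values. When no
reference exists the default is uniform draws on [0, 5] divisions, the
assay-length cap. Each of the (default) 1,000 replicates records r and
overlap; zero-variance replicates are dropped and counted. Empirical
p-values use the add-one estimator (1 + #{null ≥ obs}) / (1 + n_valid).

The null mean correlation is close to but systematically just below
zero: the two initial-copy counts of a barcode are anti-correlated by
construction (they sum to 16), and heavy-tailed 2^r growth amplifies the
effect. With 1,000 barcodes the mean stays within ±0.03.

## Synthetic data

`SyntheticConfig` defaults encode the study conditions: 500 clones per
condition; observation days 2/5/8/11; 10% highly proliferative clones at
(g = 0.75, k = 0) versus (g = 0.7, k = 0.3) for the rest; 1,000
barcodes through 4 pre-split doublings; a 50/500/500/1000-cell spike-in
ladder (one duplicated level, as in the assay design) at 20 reads/cell;
multiplicative lognormal read noise with σ = 0.2, a standard
overdispersion model at this scale chosen in the absence of a measured
read-noise model. Per-day realizations are independent (plates are fixed
and discarded at each time point), not longitudinal trajectories.

What the generator does **not** emulate: PCR chimeras and index
hopping, amplification bias, barcode sequence errors, spatial crowding,
plating losses, and any coupling between a clone's day-5 and day-8
sizes. Passing tests therefore demonstrate that the estimators recover
the truth under the stated stochastic model — not that real imaging or
sequencing noise is fully captured.

Determinism: every generator output is a pure function of its config
(seed included); derived seeds use `numpy` SeedSequence spawn keys, so
outputs are byte-identical across runs and platforms.

## Problem sizes in the test suite

The suite verifies exact oracles at 10,000 clones (Yule mean, extinction
fraction), parameter-sweep recovery at 20 seeds × 500 clones on the
0.05 grid, heritability nulls at 1,000 replicates × 1,000 barcodes, and
moment limits at n = 100,000 — sizes chosen to hold Monte-Carlo error
well below the tested tolerances while keeping a full run in minutes.

## Known limitations

- The KS sweep treats the simulation count per grid point as exact
  replication of the experiment; no correction is made for simulation
  noise in the selected optimum (the ridge tie-break mitigates, not
  removes, this).
- No likelihood-based or ABC posterior, hence no confidence regions on
  (g, k); the sweep surface itself is the uncertainty summary.
- The bootstrap option for ODE fit uncertainty is not implemented; fits
  report point estimates and cost only.
- Barcode read counts are modelled per barcode, not per read; library
  preparation artefacts are out of scope.
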