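# Methods

This note documents the models, numerical choices and limitations of
`divscape`'s components, in the order data flows through the pipeline.

## Coalescent window simulator

Each 5-kb window is one non-recombining locus: a genealogy of `n_hap`
lineages under the standard coalescent with time-varying population
size, then infinite-sites mutations at rate θ/2 per unit of coalescent
time (time in units of 2N generations of the reference size implied by
θ). Under constant size this gives Watterson's E[S] = θ·a₁ with
a₁ = Σ_{i<n} 1/i, which the tests verify to 2%.

Demographies are backward-time relative size functions r(t):
*constant* r = 1; *bottleneck* r = severity for t < t_event and 1
deeper in time (a recent contraction — fast recent coalescence, long
retained internal branches, hence less diversity and positive Tajima's
D); *growth* r(t) = exp(−g·t) (recent expansion — star-like trees,
negative D). Piecewise-constant epochs are simulated by epoch-wise
exponential waiting times with redraws at boundaries; exponential
growth by inverting the integrated hazard in closed form.

Default demographic parameters were calibrated once so the synthetic
invasive/native contrast is qualitatively realistic for this system:
bottleneck severity 0.05 at t_event 0.05 gives median window D ≈ +0.56
and roughly half the diversity of a native population expanding at
rate 2.0 (median D ≈ −0.34). No real demographic estimates exist for
these populations, so these are illustrative scenario values, not
inferences.

Mutations land on branches proportionally to length; positions are
distinct uniform integers in the window (infinite sites at 5-kb scale;
θ in the simulator is capped at 400 per window where extreme landscape
draws could otherwise exceed one variant per base pair). There is no
intra-window recombination: at the 5-kb scale the windowed summaries
analyzed here do not require it, and the simulator stays exact and
fast.

## Landscape generator

Per-window log θ for population *p* is
`log_theta_mean + shared_w + pop_effect_{p,w}` with the shared effect
split into a recombination-aligned component (weight
`baseline_rec_corr`, default 0.4 — mimicking linked selection
depressing diversity in low-recombination regions of *every*
population) and free landscape noise, all scaled to `landscape_sd`.
Bottlenecked populations receive an extra multiplicative θ penalty
whose log is linear in the rank-transformed recombination rate: a
latent Gaussian correlated with the recombination ranks at
`rec_landscape_corr` is rank-transformed back to (0,1) and multiplied
by `loss_scale` (default 0.8, i.e. up to ~55% extra θ loss in the
lowest-recombination windows).

A note on attainable landscape correlations: the coalescent's own
genealogical noise has Var(S|θ) = θa₁ + θ²a₂, whose θ² term scales
exactly like the landscape signal. At `landscape_sd = 0.5` the
between-population Spearman ρ of windowed S therefore saturates near
0.5–0.7 no matter how large θ or how many windows are simulated.
Recovery tests use `landscape_sd = 0.8` with θ = 20 as the
"strong shared landscape" condition (ρ ≈ 0.65–0.7) and
`pop_sd = 0.8, landscape_sd = 0` as the independent condition
(|ρ| < 0.1).

The multi-species distance-decay scenario
(`simulate_divergence_decay`) evolves each taxon's log-θ field by
Brownian drift of variance proportional to its divergence time and
mutates a root sequence with per-site probability proportional to the
same time, so landscape correlation falls — and sequence distance
rises — with divergence. The Mantel test between the ρ-matrix and the
√(1 − identity) distance matrix is then negative by construction of
the mechanism, not of the statistic.

What the generator does **not** emulate: linked selection as a process
(the rec-dependent loss is a phenomenological θ penalty), gene
conversion, selection, sequencing error, structural variation, or
realistic chromosome structure. Passing recovery tests therefore shows
the *statistics* behave correctly under the assumed generative
structure, not that the biological mechanisms are identified in real
data.

## Windowed statistics

Coordinates are 0-based half-open internally; VCF (1-based) and GFF3
(1-based inclusive) convert at I/O boundaries only. S counts sites
with ≥ 2 distinct non-missing alleles. π sums per-site
[n_s/(n_s−1)]·2p̂(1−p̂) over segregating sites (n_s = non-missing
haplotypes at the site) and divides by accessible sites by default;
the fixed-window-length denominator is available via
`pi_denominator="nominal"` since the convention differs between tools.
Tajima's D uses the 1989 constants with n equal to the fixed sampled
haplotype count even at sites with missing data — a documented
approximation; D is NaN exactly when S = 0. Hudson's F_ST is the
ratio-of-sums estimator per window, NaN when the summed denominator is
zero. Sites with missing-call fraction above 0.5 (the
"fewer than two of four individuals" filter) are dropped at load time.

The sign binomial test doubles the smaller exact tail (computed in
integer arithmetic, so p-values at p = 1/2 are exact) and caps at 1;
tail-doubling reproduces the printed 0.035 for 12 of 15. The
gene-proximity GLM is a log-link Poisson regression of S on proximity
class; the invasion-status interaction model runs, by default, on
per-window medians of S across the populations of a status class,
with a raw-window mode available since either level of aggregation is
defensible.

## Landscape correlations and Mantel test

Spearman matrices use pairwise-complete windows (maximizing windows
per pair, with per-pair n reported). Every ρ is reproducible by
rank-then-Pearson, which the tests assert to 1e-12 against an
independent implementation. The randomization null redraws k windows
uniformly (default matching the 2,714-window BUSCO set size when
available) for 100 iterations and reports empirical quantiles.

The Mantel statistic is the Spearman correlation of the off-diagonal
upper triangles; the null permutes rows and columns of one matrix
simultaneously. Because rank transforms commute with simultaneous
row/column permutation, the triangles are rank-transformed once and
permutations recompute only a Pearson correlation. p = (1 + #extreme)
/ (1 + n_perm), two-sided on |r| by default with one-sided options;
10,000 permutations by default. The distance-decay check is asserted
one-sided (`alternative="less"`): the hypothesis is directional, and
with seven taxa the two-sided permutation p floor lies near 0.05.

Distances from concatenated alignments follow the √(1 − identity)
convention with gap/ambiguity sites excluded pairwise; the raw
proportion-different matrix is also returned. The invasive-vs-native
comparison reports, per "other" taxon, whether the mean ρ to invasive
populations is weaker than to native populations, plus an exact sign
test and a 2×2 exact test on [weaker, not-weaker] × [invasive,
native]. Both statistics are emitted because the weaker/stronger
comparison can reasonably be tabulated either way.

## Recombination analyses

The scaled-difference statistic restricts to windows whose
across-native-population mean S lies in a band (default 150–300 segregating
sites per 5-kb window, a band typical of African *Z. indianus*
samples), partitions them into equal-count
recombination-rate quantile bins (default 20; sensitivity across
{10, 20, 50} is a one-line loop for the caller), and per bin computes
Δ = mean_inv(S) − mean_nat(S) scaled by the bin's overall mean S; the
headline number is the Spearman correlation of scaled Δ with bin mean
recombination rate, with the raw-Δ version reported alongside. All
recombination statistics are rank-based and thus invariant to affine
rescaling of the map. Windows without a recombination estimate are
excluded, not imputed.

One interaction worth knowing: with a recombination-correlated base
landscape, the native-mean-S band truncates high-θ windows and can
induce a positive scaled-difference correlation even when the
bottleneck loss is recombination-independent. The specificity test
therefore decouples recombination from the base landscape
(`baseline_rec_corr = 0`) to isolate the loss mechanism; the same
caveat applies to interpreting the statistic on real data.

## Hierarchical thermal performance model

Counts y (adult progeny per pair) at temperature T follow a negative
binomial with mean f(T) and shared dispersion k (variance
μ + μ²/k; Poisson by config flag). The curve family is the
mode-normalized Kumaraswamy kernel given in the README; normalizing by
the kernel's mode value makes `stretch` exactly the maximum height.
A_c has the closed form stretch/k(x\*) · (T_max − T_min)/(a·b) via the
Beta integral, and B_50's area quantiles invert the kernel CDF
1 − (1 − x^a)^b analytically; both are verified against 10⁵-point
trapezoid grids to 0.1%. B_50 is the central-50%-area width by default
(the temperatures at which cumulative area reaches 25% and 75% of
A_c); a half-height-width alternative is provided (`method="height"`)
since "niche breadth" admits either reading.

Population-level parameters live on an unconstrained scale
(log stretch, log(a−1), log(b−1), T_min, log(T_max − T_min)) and are
partially pooled: z_{pc} ~ N(μ_c, σ_c²) with μ_c ~ N(m₀, s₀²) and
σ_c² ~ Inv-Gamma(ν₀/2, ν₀τ₀²/2) (ν₀ = 4). The inverse-gamma family
was chosen for exact conjugate Gibbs updates of the hyperparameters;
defaults (e.g. stretch centred on 60 progeny, T_min on 9 °C, thermal
range on 22 °C, all weakly informative) target fruit-fly fecundity
curves on a 5–35 °C range and are carried in one `TPCConfig` object
logged with every fit.

Sampling is Metropolis-within-Gibbs: all populations' 5-parameter
blocks are proposed simultaneously (they are conditionally independent
given the hyperparameters) with Haario-style adaptive covariance
proposals, three inner proposals per sweep; the shared log dispersion
takes a scalar Metropolis step; hyper means and variances are drawn
exactly from their conditionals. Observations collapse onto unique
(population, temperature) cells, so a sweep costs ~8 curve evaluations
per population. An earlier affine-invariant ensemble version could not
mix the 61-dimensional joint space at practical budgets; the Gibbs
scheme reaches split R-hat ≤ ~1.02 in a few seconds per fit.

Two independent chains (default 10,000 sweeps, 3,000 burn-in, thin 5)
feed arviz's split R-hat and ESS; any R-hat > 1.05 raises by default.
Calibration studies that fit many replicates pass
`on_bad_rhat="warn"` so one slow replicate cannot abort the study —
the R-hat values are still recorded in the returned object. The
pairwise comparison rule calls two populations different when
max{P(θᵢ > θⱼ), P(θᵢ < θⱼ)} > 0.95 over aligned joint draws (ties
split evenly so exchangeable draws give exactly 0.5); letter groups
come from greedy coloring of the non-difference graph. In the recovery
study (10 populations × 8 assay temperatures spanning 13.9–28.9 °C ×
12 pairs, 20 replicate fits) 95% credible intervals cover the
generating values in ≥ 85% of population×parameter cells and the 0.95
rule falsely separates equal-parameter pairs in ≲ 10% of cases. T_min
and T_max are only weakly identified by the assayed temperature range,
so their posteriors lean on the (truthful) hyperpriors; widening the
temperature design shrinks them.

## Niche–diversity models and pipeline

The niche link is ordinary least squares of each derived parameter on
median windowed S, with an explicit one-population-per-species subset
mode; degenerate (constant-S) designs return F = 0, p = 1 rather than
erroring. The pipeline expands one global seed into per-stage child
seeds via `SeedSequence.spawn`, serializes the resolved config and
seeds into the output directory, and is bit-identical on rerun. Stage
problem sizes in the default config (400 windows, 4 populations, 4
thermal populations) were chosen to exercise every stage in a couple
of minutes on one CPU; all are config knobs.

## Known limitations

- Missing-data Tajima's D uses the fixed sample size in its constants
  (exact only for complete data).
- The simulator's rec-dependent loss is phenomenological; it
  reproduces the pattern, not the mechanism, of linked selection.
- The per-window coalescent ignores intra-window recombination and
  correlation between adjacent windows, so windowed statistics are
  independent across windows in a way real genomes are not.
- The TPC likelihood family (negative binomial) and the curve
  parameterization are reasonable choices where the original
  description is not explicit; both sit behind `TPCConfig` /
  `tpc_value` so alternatives can be swapped without touching callers.
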