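# Methods

This note documents the models, estimators and numerical choices behind
`occupre`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Element scoring and dependence classification

Each catalog element (~1 kb) is scored per library as the mean read
density of the `window` (default 6) consecutive positions with the
highest counts inside the element. A window-maximum statistic is used
rather than the interval mean because binding footprints occupy only a
small part of a 1 kb element and the maximum is insensitive to how much
flanking background the interval includes. Raw scores are normalized to
reads per million of the library's total depth; the scale constant is
arbitrary since it cancels in every cross-genotype contrast.

Replicate scores are checked by Pearson correlation over elements, with a
configurable QC gate at r > 0.90; correlation is meaningful here only
because element strengths span a wide dynamic range (see the generator
below). Replicate scores are averaged *before* contrasting — the
contrast is `RD(mean of reps)`, not the mean of per-replicate RDs —
because per-replicate RDs weight noisy low-coverage replicates equally.

The contrast is the symmetric relative difference `RD = 2(m−c)/(m+c)`
with companion ratio `m/c`. The two are monotone transforms of one
another (`RD = 2(ratio−1)/(ratio+1)`), so they can be displayed as two
scales of one axis. RD is preferred for classification because it is
bounded (−2, 2), antisymmetric under genotype swap, and invariant to any
per-library depth rescaling. Classification thresholds default to
RD < −1.0 (dependent; in ratio terms, the mutant retains less than a
third of control signal) and RD > −0.5 (independent; more than ~60%
retained).

Catalog filtering removes (1) elements overlapping any exclusion
interval by at least one base — used for genotype-specific deletions,
where the mutant signal is trivially absent — and then (2) elements with
weak control signal. "Weak" defaults to the lower 30% of the dynamic
range, i.e. score < min + 0.30·(max − min) computed over the elements
that survived step (1); a 30th-percentile rule is available
(`weak_mode="quantile"`) since the range fraction and the quantile differ
substantially on long-tailed score distributions. When all scores are
equal the range rule is disabled with a warning. Filtered elements carry
a reason (`deletion_overlap` / `weak_signal`) and no class.

The ChIP RD distribution is compared against the input RD distribution
(computed identically on input tracks over the same elements) with a
two-sided Wilcoxon rank-sum test: exact null for small untied samples,
normal approximation with continuity and tie correction otherwise,
matching R's `wilcox.test` defaults.

## Peak calling

The genomic background is the mean and *population* SD of per-base values
over the entire analyzed track, zeros included; trimming would make the
threshold depend on arbitrary quantile choices, and including signal
bases only makes the 3-SD rule conservative. Significant regions are
maximal clusters of coordinates exceeding mean + 3·SD in which successive
supra-threshold coordinates are separated by at most 500 bp of
sub-threshold bases. Clusters with fewer than `window` (6)
supra-threshold coordinates are discarded: the summit is defined as the
center of the six consecutive coordinates with the highest counts, which
a sparser cluster cannot support — such clusters are stray noise
coordinates or the sparse far edge of a decaying flank. The summit is the
floor-midpoint of the leftmost maximal-sum window (deterministic
tie-break). Peaks are called on the replicate-averaged, depth-normalized
track; calling per replicate and intersecting is a config-level variant,
not a different algorithm. Isolated peaks have nearest-neighbor summit
distance strictly greater than 10 kb on the same chromosome.

If the 3-SD threshold is applied to raw instead of depth-normalized
densities the calls are identical, because mean and SD are computed on
the same track that is thresholded.

## Profiles and the distal-loss readout

Profiles are built per replicate as 100 bp-binned mean densities over
±5 kb around isolated summits, averaged across replicates, then averaged
over peaks; the peak-averaged profile is smoothed by loess with span 0.1.
Loess here is locally *quadratic* regression with tricube weights over
the `floor(span·n)` nearest neighbors and no robustness iterations; the
implementation reproduces linear and quadratic inputs exactly and agrees
with R's `loess(..., degree = 2, surface = "direct")` to machine
precision (frozen cross-check in `tests/data/loess_reference.tsv`; the
series there is synthetic). Pointwise 95% bands, when requested, are
percentile bootstrap over peaks (500 resamples, seeded) — a choice among
several defensible interval constructions, recorded here because peaks,
not bins, are the exchangeable units.

The genotype contrast evaluates both fitted curves at 50 evenly spaced
offsets, subtracts (mutant − control) and smooths the 50 differences with
loess span 0.2. By default (`scale="summit"`) each curve is first
background-subtracted and divided by its own summit excess, where the
background is the mean of 999 randomly placed 100 bp bins having zero
overlap with any called region (bins may overlap each other; a disjoint
mode exists for small genomes). Summit scaling is what makes "lost more
at a distance than at the summit" a well-posed comparison: on the
absolute scale the summit term dominates trivially, and without
background subtraction the flat sequencing background — which does not
attenuate — masquerades as retained distal signal. The unscaled
difference (`scale="none"`) is also available. The headline readout,
`distal_vs_summit()`, compares the mean |difference| over offsets
2–5 kb with the |difference| at offset 0.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
per base x and library with depth factor d:

* control ChIP rate: `d·b·[1 + (A_i − 1)(c_i(x) + t_i(x))]`
* mutant ChIP rate: `d·b·[1 + (A_i·a_s − 1)c_i(x) + (A_i − 1)a_t t_i(x)]`
* input rate: `d·b`

with background b = 0.5 reads/bp and per-element control summit
amplitudes A_i log-normal with mean 20 and CV 0.4 — element strengths
must vary for replicate score correlation to be a meaningful QC, as it is
on real element catalogs. The core envelope c_i is a 200 bp plateau (a
flat top wide enough that the top-6-window statistic and the summit are
well defined) stepping down to 0.85 immediately outside the footprint and
decaying with 150 bp half-life — the pointed apex and fragment-size
shoulder of real summit shapes. The tail envelope t_i is zero inside the
element (the element core is nucleosome-depleted), starts at 0.15 of the
plateau excess at the element boundary and decays with 2 kb half-life out
to 5 kb — low-level, kb-scale flanking signal an order of magnitude
weaker than summit binding, as looping-contact crosslinking appears in
real data.

Summit attenuation a_s is defined on the summit *total* (mutant summit
coverage = a_s × control summit coverage) and scales the whole core
envelope; tail attenuation a_t scales the tail *excess over background*
(background reads do not attenuate). When no tail attenuation is
configured, a_t defaults per element to `(A_i·a_s − 1)/(A_i − 1)`, the
retention under which the mutant element excess is a uniformly scaled
copy of the control — the correct no-distance-preference null. Note that
setting a_t = a_s is *not* that null: because a_s acts on the total and
a_t on the excess, it retains slightly more tail than proportional loss
and induces a small systematic distal difference. The two
parameterisations also make the mutant envelope mildly discontinuous at
the element boundary when a_t differs from the proportional value; this
is a deliberate consequence of defining summit attenuation on totals.

Counts are Poisson per base (analytic expectations; e.g. mean mutant
summit coverage per class is exactly b·A·a_s, the 1.0/4.0/9.0 reads/bp of
the reference configuration), with a negative-binomial option
(gamma-Poisson, `var = μ + α·μ²`) for the overdispersion of real
coverage. Each track's `total_depth` is the notional genome-wide library
size `d·b·genome_size` (default 120 Mb): the simulated 2 Mb chromosome
stands for a window of a larger genome, so depth normalization behaves as
for real libraries in which reads inside binding sites are a negligible
fraction of the total. Default depth factors are unequal
(1.0/1.3 control, 0.8/1.1 mutant), mirroring real library-size spread.
Elements are placed with ≥25 kb spacing and a boundary margin, so
isolation and background sampling are well defined; multi-chromosome
studies are config repeats, not special cases.

What the generator does **not** emulate: mappability and alignment
artifacts, PCR duplicates, GC bias, copy-number variation, correlated
(fragment-level) noise between neighboring bases, and input tracks with
chromatin-accessibility structure. Tests passing on these simulations
therefore demonstrate the estimators' correctness and power under the
assumed signal model, not robustness to those real-data pathologies.

## Problem sizes and determinism

Simulation-based tests run on 2 Mb chromosomes with 60 elements and two
replicates per genotype (scaled-down 0.4–0.6 Mb studies for smoke tests),
sizes at which every generative expectation used in testing has
Monte-Carlo error well below the asserted tolerances. All randomness
flows through `numpy.random.default_rng` seeds carried in configs; a full
pipeline run writes no timestamps into its outputs, so identical inputs,
config and seed reproduce the report bundle bit for bit.

## Known limitations

* Single-chromosome orchestration: the library scores arbitrary
  chromosomes, but `run_pipeline` handles one chromosome per run.
* bedGraph carries no chromosome length; trailing zero coverage is
  restored by zero-padding tracks to a common length at load time (the
  generator writes explicit zero runs to avoid ambiguity).
* The threshold-and-cluster caller is not FDR-calibrated; the 3-SD rule
  is the analysis's definition, not a significance guarantee.
* Fragment-length estimation uses plain strand cross-correlation of
  5′-end densities with a smallest-shift tie-break; phantom-peak
  artifacts of low-quality libraries are not modeled.
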