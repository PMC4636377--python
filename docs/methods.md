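# Methods

## The simulation model

`evotrace.simulate` implements a discrete-generation Wright–Fisher model
over asexual lineages. A lineage is a genotype class; each generation the
population of `population_size` cells is multinomially resampled with
Wrightian fitness `w_i = exp(s_i · stress(t)/stress(0))`, where `s_i` is
the summed selection coefficient of the lineage's mutations. Using the
Malthusian form `e^s` (rather than `1 + s`) makes the expected trajectory
of a lineage with constant advantage follow the continuous logistic
`f(t) = f0·e^{st} / (1 − f0 + f0·e^{st})` exactly, which is the closed form
the tests check against.

Mutation supply is split into beneficial (`beneficial_rate`, selection
coefficients drawn Exponential(`dfe_mean`)) and neutral hitch-hiker
(`neutral_rate`) classes, each further split SNP/indel by `snp_fraction`
(default 0.72). Every new mutation founds a new lineage perfectly linked to
its background — there is no recombination, matching asexual propagation. A
mutation's population frequency is therefore the clade frequency of the
lineage it founded.

**Stress schedule.** The default schedule steps the ethanol level from 6%
(v/v) up to 12% at generation 200, raised every 25 generations. Selection
coefficients of tolerance mutations scale with the current level relative
to the starting level (`s_eff = s · stress(t)/stress(0)`, so advantages
double over the ramp): a tolerance allele is worth more the harsher the
environment. With a constant schedule `[(0, 1.0)]` the scaling is inert,
which the closed-form tests use.

**Events.** A mutator (`MutatorSpec`) multiplies the supply of one mutation
class (SNP or indel) by a configured fold in its descendants; a ploidy
event founds a diploidised lineage with a configured advantage. Both take
over the currently most frequent lineage at onset — the event background is
treated as established rather than being given one founding cell, since an
event observed in the data is conditioned on its own survival.
`PlantedLineage` inserts a lineage with fully known truth (onset, parent,
advantage, starting fraction, number of linked tag mutations); planted
lineages are the ground truth used by the cohort, Muller and estimator
validations. An optional `death_rate` thins the effective census
(divisions, not wall-clock, are what generations count).

**Calibration.** The default preset runs 200 generations at
`population_size = 1e5` — a deliberate scale-down from the experiment's
~1e10 cells, at which per-cell bookkeeping would be meaningless — with
sequencing observed at generations 0, 40, …, 200 at 500× (population) and
80× (clones), three clones per time point, 500-bp depth bins. Default
supply (`beneficial_rate = neutral_rate = 6e-5` per genome per generation,
`dfe_mean = 0.15`) was chosen so a default run shows the qualitative
dynamics of the study system: over the run, a dozen-plus mutations sweep
above the 10% detection band in a handful of linked cohorts, with some
cohorts declining or going extinct after their maximum (clonal
interference). These parameter values are a calibration of the scaled-down
system, not estimates of the organism's rates; the per-population supply
N·U, not U itself, is the meaningful quantity.

**Observation model.** Population allele frequencies are observed as
Binomial(depth, f)/depth with depth ~ Poisson(coverage) per site; a
heterozygous mutation on a diploid background is sequenced at half its cell
frequency. Clones are drawn per time point without replacement among live
genotype classes, proportional to frequency (with replacement only if
fewer distinct classes than colonies exist). Depth tracks are per-bin
Poisson counts with mean `coverage · bin_size / read_length` (read-length
proxy 100 bp), scaled by `copy_number / 2` inside planted CNV segments
carried by the clone's ancestry. Competition assays follow
`ln(U/R)(t) = ln(U0/R0) + s·t` plus Gaussian noise, with endpoint counts
consistent with the series; fluorescence series exponentiate the same
log-ratio into two background-inflated channels in either dye orientation.

What the generator does **not** emulate: read-level errors and mapping
artifacts, GC/mappability coverage waves, sub-telomeric repeat families
(the sub-telomeric filter is exercised by position only), linked
recombination (absent in this system), stress-dependent death and
generation-time distortion (only the census thinning above), and any
chemistry of the medium. Passing tests therefore show the pipeline's
operations are correct on idealized sequencing noise — not that they are
robust to artifacts the generator does not model.

## Variant processing

Positions are 1-based inclusive. Sub-telomeric removal drops
`position ≤ 15000` or `position > length − 15000` (chromosomes shorter
than 30 kb lose everything); the margin is configurable. The "changed by
more than 10%" rule is read as the absolute frequency range with a strict
inequality (a 1e-12 guard absorbs float rounding at the boundary); a
relative variant is available behind a flag. Missing frequencies are
treated as not-sequenced, not zero; leading gaps are set to 0 and interior
gaps linearly interpolated only when building a complete trajectory matrix.
Ancestral variants are removed by site-key (chromosome, position, ref,
alt) difference. The heterozygous-frequency adjustment doubles the
reported frequency (capped at 1) when a variant is heterozygous in *all*
clones of a time point and the population allele frequency is within
±0.10 of 0.5 — the band exists because sequencing noise makes exact-50%
a measure-zero event; every adjustment is logged.

## Cohorts and Muller nesting

Clustering is complete-linkage agglomerative on Euclidean distance between
frequency vectors, cut at a threshold (default 0.3): complete linkage
guarantees every within-cohort pairwise distance is below the threshold,
which is the operational meaning of "moves together". Rows are sorted by
mutation id before clustering so ties merge deterministically and the
partition is permutation-invariant. The expected distance between two
noisy copies of the same trajectory at 500× over six time points is
~`sqrt(6 · f(1−f)/500)` ≤ 0.08, well under 0.3, while distinct sweeps
differ by O(1).

Nesting is inferred by containment: cohort B nests in A if A's origin
(first generation with positive mean) precedes B's and
`freq_B(t) ≤ freq_A(t) + ε` wherever B is present (`ε = 0.02`, about two
binomial standard errors at 500× and f ≈ 0.1). Among eligible parents the
one with the smallest mean excess — the tightest envelope, which is the
immediate parent rather than a grandparent — wins. Cohorts violating
containment for every candidate are placed top-level with a warning. The
residual ancestral fraction is 1 minus the top-level sum. Decliners are
flagged from the running maximum: a mutation declines if any later
observation sits more than 0.10 (strict) below the maximum reached so far;
extinction means positive somewhere and exactly zero at the final observed
generation.

The exported Muller JSON schema: `{generations: [int], residual_ancestral:
[float], cohorts: [{label, members, parent, origin, frequency: [float]}]}`,
plus a long-format TSV (`cohort, parent, generation, frequency`) for
plotting.

## CNV segmentation

Counts are accumulated in 500-bp bins; bins with fewer than 10 reads are
masked. Log2 ratios are taken against the genome-wide median of unmasked
bins (robust to focal events; an `ploidy` option rescales the expectation
for non-diploid clones). Segmentation is a circular-binary-segmentation
scan: within each window every interior segment `[i, j)` with at least 5
bins (and flanks of at least 5 bins or zero) is tested against the rest by
Welch's t over "evidence" bins — the central 95% per chromosome; the
trimmed 5% still receive their segment's call — and the window splits at
the most significant pair if p < 1e-9, recursing into all parts. Because
the scan can carve one event into several pieces, adjacent segments whose
means do not differ at the same threshold are merged back, and each
boundary is finally re-located at the least-squares optimum of the local
two-mean model. At 80× coverage (≈400 reads/bin) the per-bin log2 noise is
≈0.07, so a single-copy change (0.58) is an ≈8-sigma shift and ≥25-bin
events are recovered with essentially full power, while the 1e-9 threshold
holds the neutral false-positive rate per chromosome well under 1%. Calls:
gain at mean log2 ≥ +0.25, loss at ≤ −0.25; the display bands (0.23–0.58
gain, −1 to −0.23 loss) are annotated independently of the call, as the
two conventions serve different purposes (calling vs plotting). Whole-
chromosome aneuploidy is flagged when ≥90% of a chromosome's bins share
one non-neutral call.

## Gene recurrence

`P(X ≥ k)` is computed with the regularized-incomplete-beta survival
function (scipy), which matches arbitrary-precision rational summation to
better than 1e-12 relative on the tested grid. The upper tail, not the
point mass, is used: a point probability is not a test statistic. Distinct
positions are counted per gene; hits identical at the nucleotide level are
collapsed first. Benjamini–Hochberg adjustment across genes is the default
(`--adjust none` disables). The aggregate Monte-Carlo test drops n
mutations multinomially with per-gene probability L/G and compares
*cumulative* counts (genes hit ≥ m times) against the observed census
accumulated the same way — the cumulative statistic is monotone in signal
and saturates to p = 1 when n is huge, which the exact-m count does not.

## Fitness estimation

Endpoint: the log-ratio formula, with zero counts rejected (pseudo-counts
are a user decision, not a silent default). The non-fluorescent fraction φ
inflates reference counts to R/(1−φ) and removes the same cells from the
unlabeled pool; the marker cost is applied to s (s_adj = s_raw + s_m),
flagged in the CLI output since applying it to counts instead would be a
different convention. Slope mode fits ln(background-corrected
mutant/reference) against generations by iteratively reweighted least
squares with bisquare weights (ordinary least squares below 4 points),
negates swapped orientations, subtracts the parental-control slope, and
pools replicate slopes (mean ± SEM). The concentration-response comparison
is a one-way ANOVA over replicate s values with Welch t contrasts against
the 0% condition.

## Sub-network inference

Edge probabilities come from the out-degree distribution of edge terminal
nodes: `p(u→v) = p_min + (p_max − p_min)·(1 − rank)` with average
percentile ranks over all edges' terminal nodes and (p_min, p_max) =
(0.1, 0.9). This reproduces the intended ordering — edges into hubs are
improbable — with bounded probabilities; the exact functional form is a
design choice. K-best path search is a best-first expansion on path
probability (product of edge probabilities) over loop-free paths of at
most 4 edges, pruning partial paths below the 0.01 cutoff; ties break on
the lexicographic node sequence, so output is fully deterministic.
Sub-network selection visits candidate paths (k best per ordered mutated
pair) in decreasing probability and accepts a path when its probability
exceeds `cost ×` (number of edges it would newly add), iterating until no
candidate qualifies; accepted edges make overlapping paths cheaper. The
score is the path probability itself, not its logarithm: with log-scores
no path could ever clear a positive per-edge cost (log p ≤ 0), whereas on
the probability scale the published cost presets (0.25 for the combined
list, 0.05 per small list, 0.5 for large mutator lists) act as direct
probability floors on a single new edge. On edge-disjoint candidate
families this greedy rule provably maximizes Σ p_path − cost·|edges|,
which the brute-force oracle test exploits. No claim of output-identity
with the original PheNetic implementation is made; its exact edge-
probability map and objective are not public.

## Problem sizes used in validation

The validation suite runs planted-truth recoveries at the scales the
package targets: 100 seeded cohort simulations (4 planted cohorts, 9
mutations, 7 time points) for clustering accuracy at 500× noise; 10–20
simulated clones with planted 50-bin gain and loss events plus 1000
neutral 200-bin chromosomes for the CNV caller; 100 replicate competitions
per estimator; a (n ≤ 1000, k ≤ 10) grid for the binomial tail; 100 random
8-node graphs for path-search exactness. The logistic-growth check uses
N = 5×10^5 and 100 replicates, where the O(1/N) nonlinearity bias of the
frequency map stays inside Monte-Carlo error.

## Known limitations

- Generations are division counts; under near-lethal stress with heavy
  death the mapping to wall-clock time and to mutational opportunity is
  not modelled beyond the census-thinning death rate.
- Cohort inference is frequency-correlation only; mutations with similar
  trajectories on different backgrounds cannot be separated without
  read-level phasing, and near-equal-frequency nesting is genuinely
  ambiguous (validated only against simulator truth).
- The CNV caller assumes a flat expected coverage per bin; real tracks
  need GC/mappability normalization upstream.
- The recurrence test conditions on total coding hits and gene length
  only; it ignores site-level mutability differences.
- Sub-network selection is greedy, not exact, off the edge-disjoint case.
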