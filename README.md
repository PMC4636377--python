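# evotrace

Mutational dynamics of evolve-and-resequence experiments, end to end: from
population allele-frequency trajectories and clone read-depth tracks to
haplotype cohorts and Muller diagrams, clonal-interference statistics,
CNV/aneuploidy calls, recurrently-hit-gene tests, selection-coefficient
estimates, and probabilistic sub-network inference over a gene-interaction
graph. A fully seeded synthetic-data generator provides ground truth for
every stage.

The package is aimed at experimental-evolution studies of the
"evolve-and-resequence" kind — e.g. yeast populations propagated for
hundreds of generations in turbidostats under a rising ethanol ramp, with
periodic whole-genome sequencing of the population (~500×) and of isolated
clones (~80×).

## What it computes

**Variant processing.** Trajectory tables (TSV or VCF) are cleaned with the
standard final-processing rules: variants in sub-telomeric regions (15 kb
from the chromosome ends) are dropped; population variants whose frequency
never changes by more than 10% (absolute, strict) are dropped; for haplotype
reconstruction, multi-allelic sites, variants with mixed zygosity across
clones, and variants that never reach a frequency of 0.2 are excluded.
Mutations heterozygous in all clones of a time point and near 50% allele
frequency are reported at the cell-level frequency (doubled).

**Haplotype cohorts and Muller diagrams.** Trajectories are clustered by
complete-linkage agglomerative clustering on the Euclidean distance between
frequency vectors; a cohort's frequency is the mean of its members. Cohorts
are nested by frequency containment into a Muller forest, and
clonal-interference statistics (extinct mutations; mutations dropping > 10%
after their maximum) are reported.

**CNV calling.** Read counts are accumulated in 500-bp bins (bins with < 10
reads rejected), converted to log2 ratios against the genome-median diploid
expectation, and segmented by a circular-binary-segmentation-style scan
(Welch t-test, p < 1e-9, minimum 5 bins per segment, 5% outlier trimming).
Segments are called gain/loss at mean log2 ±0.25; a single-copy gain in a
diploid sits at log2(3/2) = 0.58 and a hemizygous loss at log2(1/2) = −1.

**Gene recurrence.** A gene of coding length L hit k times among n coding
mutations is tested with the binomial upper tail P(X ≥ k), X ~ Binomial(n,
L/G), G the genome's total coding content; an aggregate Monte-Carlo test
asks how often random placement produces as many multiply-hit genes.

**Fitness.** From endpoint competition counts, s = (ln(U_f/R_f) −
ln(U_i/R_i))/T with relative fitness 1 + s, including corrections for
labeled-but-non-fluorescent cells and marker cost; from two-colour
fluorescence time series, a robust (bisquare) slope of ln(mutant/reference)
per generation with dye-swap pooling and control normalization, plus a
one-way ANOVA across ethanol concentrations.

**Sub-network inference.** A typed interaction network (metabolic,
protein-protein, protein-DNA) is probabilized so that edges into
high-out-degree hubs become improbable; mutated genes are connected through
k-best (default 100) loop-free paths of at most 4 edges with a 0.01 search
cutoff, and a parsimonious sub-network is grown greedily under a per-edge
cost.

## Worked example

Simulate a 200-generation experiment under the default study-like
calibration, filter the observed population trajectories, and reconstruct
cohorts:

```
$ evotrace simulate --seed 7 --out-dir sim
wrote 2423 variants, 18 clone depth tracks to sim

$ evotrace filter sim/trajectories.tsv --genes genes.bed \
    --chrom-lengths chroms.tsv --out filtered.tsv
kept 12/2423 variants (182 sub-telomeric)

$ evotrace haplotypes filtered.tsv --out muller.json
6 cohorts; 1 extinct, 1 decliners of 12 mutations

$ evotrace cnv sim/depth_g200_c0.tsv --out segments.bed
8 segments, 0 non-neutral
```

Of 2423 mutations that ever appeared in the simulated population, 12 rose
or fell by more than 10% — these are the sweeps and their passengers; the
rest drifted at low frequency. The 12 group into 6 linked cohorts, one of
which was outcompeted (extinct) after declining from its maximum — clonal
interference. The clone's depth track contains no planted CNV, and no
segment is called. `muller.json` holds the nesting: here every later cohort
arose on the background of the first sweep (`C02`–`C06` nested in `C01`).

Fitness from three replicate endpoint competitions (simulated with
s_true = 0.08, 2% non-fluorescent reference cells):

```
$ evotrace fitness competition.tsv --mode endpoint --phi 0.02
s = 0.0815 +/- 0.0014 (fitness 1.0815, n=3, marker cost applied to s)
```

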