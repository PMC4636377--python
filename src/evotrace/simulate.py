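"""Forward simulation of a turbidostat evolution experiment with known truth.

A discrete-generation Wright-Fisher model with selection over asexual
lineages: each new beneficial (or neutral hitchhiking) mutation founds a new
lineage perfectly linked to its background; mutator lineages multiply the
mutation supply of one mutation class; a ploidy-convergence event founds a
diploidised lineage with its own fitness advantage. The observation layer
re-emits the truth the way the study's sequencing did: population allele
frequencies with binomial noise at ~500x, clone genotypes from colonies
picked at each time point, and 500-bp binned read-depth tracks at ~80x with
planted copy-number events. Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, synthetic_genome

__all__ = [
    "SimConfig", "MutatorSpec", "PloidyEvent", "CNVEvent", "Mutation",
    "TrueLineage", "LineageForest", "ObservedDataset",
    "PlantedLineage", "simulate_evolution", "observe_sequencing",
    "simulate_competition", "simulate_fluorescence", "simulate_depth_track",
    "true_trajectory_table", "default_stress_schedule",
]

_READ_LENGTH_PROXY = 100  # bp per read; converts coverage to reads/bin


def default_stress_schedule(n_generations: int = 200) -> list[tuple[int, float]]:
    """Stepwise ethanol ramp: 6% (v/v) at start, raised every 25 generations,
    reaching 12% at generation 200."""
    steps = []
    for g in range(0, n_generations + 1, 25):
        steps.append((g, 6.0 + 6.0 * g / 200.0))
    return steps


@dataclass(frozen=True)
class MutatorSpec:
    """A mutator lineage arising at ``onset``: its descendants multiply the
    supply of ``mutation_class`` mutations by ``fold``."""
    onset: int
    fold: float
    mutation_class: str = "indel"  # "SNP" | "indel"


@dataclass(frozen=True)
class PloidyEvent:
    """A whole-genome ploidy-convergence event with a fitness advantage."""
    onset: int
    advantage: float


@dataclass(frozen=True)
class PlantedLineage:
    """A lineage injected with known truth: at generation ``onset`` a
    fraction ``f0`` of the parent's cells (parent = index into the planted
    list, or -1 for the founder) becomes a new background with selective
    advantage ``s`` over its parent, tagged by ``n_mutations`` new linked
    mutations."""
    onset: int
    s: float
    f0: float
    parent: int = -1
    n_mutations: int = 1
    mutation_class: str = "SNP"
    zygosity: str = "homozygous"


@dataclass(frozen=True)
class CNVEvent:
    chromosome: str
    start: int            # 0-based, inclusive of the first affected bin
    end: int              # exclusive
    copy_number: int      # absolute copies on a baseline of 2
    carrier_lineage: int | None = None  # None -> all clones carry it


@dataclass
class SimConfig:
    """Study-calibrated simulation preset.

    The defaults mirror the study conditions at desk scale: 200 generations
    with an ethanol ramp stepped every 25 generations, population sequencing
    at ~500x and clone sequencing at ~80x, three clones per time point,
    500-bp depth bins. The census size is scaled down from the experiment's
    10^10 cells (see docs/methods.md); the beneficial supply N*U is chosen
    to reproduce cohort-sweep dynamics with clonal interference.
    """
    population_size: int = 100_000
    n_generations: int = 200
    sample_generations: list[int] = field(
        default_factory=lambda: [0, 40, 80, 120, 160, 200])
    beneficial_rate: float = 6e-5
    neutral_rate: float = 6e-5
    dfe_mean: float = 0.15
    snp_fraction: float = 0.72
    mutator_spec: MutatorSpec | None = None
    ploidy_event: PloidyEvent | None = None
    stress_schedule: list[tuple[int, float]] = field(
        default_factory=default_stress_schedule)
    population_coverage: float = 500.0
    clone_coverage: float = 80.0
    clones_per_timepoint: int = 3
    bin_size: int = 500
    cnv_events: list[CNVEvent] = field(default_factory=list)
    planted: list[PlantedLineage] = field(default_factory=list)
    death_rate: float = 0.0
    baseline_ploidy: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        for name in ("beneficial_rate", "neutral_rate", "dfe_mean", "death_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 <= self.death_rate < 1:
            raise ValueError("death_rate must be in [0, 1)")
        sg = list(self.sample_generations)
        if sg != sorted(sg) or (sg and (sg[0] < 0 or sg[-1] > self.n_generations)):
            raise ValueError("sample_generations must be sorted within "
                             "[0, n_generations]")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.stress_schedule:
            raise ValueError("stress_schedule must not be empty")
        for i, pl in enumerate(self.planted):
            if not (0 < pl.f0 <= 1):
                raise ValueError("planted f0 must be in (0, 1]")
            if not (1 <= pl.onset <= self.n_generations):
                raise ValueError("planted onset outside [1, n_generations]")
            if pl.parent >= i:
                raise ValueError("planted parent must precede the lineage")

    def stress_at(self, generation: int) -> float:
        level = self.stress_schedule[0][1]
        for g, s in self.stress_schedule:
            if g <= generation:
                level = s
        return level


@dataclass
class Mutation:
    id: str
    lineage: int
    origin: int
    chromosome: str
    position: int
    ref: str
    alt: str
    mutation_class: str   # "SNP" | "indel"
    gene: str             # '' if intergenic
    zygosity: str         # "homozygous" | "heterozygous"
    s: float


@dataclass
class TrueLineage:
    """One genetic background; ``frequency`` is the clade frequency
    (the lineage plus all its descendants), i.e. the frequency of the
    mutations that founded it."""
    id: int
    parent: int | None
    origin: int
    mutation_ids: list[str]
    s: float
    ploidy: int
    mutator_fold: dict[str, float]
    frequency: np.ndarray = field(default_factory=lambda: np.zeros(0))


class LineageForest:
    """Full simulation truth: lineages, mutations and frequency matrices."""

    def __init__(self, lineages: list[TrueLineage], mutations: list[Mutation],
                 genotype_freq: np.ndarray, config: SimConfig,
                 genome: GenomeAnnotation):
        self.lineages = lineages
        self.mutations = mutations
        self.genotype_freq = genotype_freq  # (n_lineages, n_generations+1)
        self.config = config
        self.genome = genome
        self._children: dict[int, list[int]] = {}
        for lin in lineages:
            if lin.parent is not None:
                self._children.setdefault(lin.parent, []).append(lin.id)
        clade = genotype_freq.copy()
        for lin in sorted(lineages, key=lambda l: -l.origin):
            for ch in self._children.get(lin.id, []):
                clade[lin.id] += clade[ch]
        self.clade_freq = clade
        for lin in lineages:
            lin.frequency = clade[lin.id]

    def children(self, lineage_id: int) -> list[int]:
        return self._children.get(lineage_id, [])

    def ancestry(self, lineage_id: int) -> list[int]:
        """Lineage ids from the founder down to ``lineage_id`` inclusive."""
        path = []
        cur: int | None = lineage_id
        while cur is not None:
            path.append(cur)
            cur = self.lineages[cur].parent
        return path[::-1]

    def mutations_of(self, lineage_id: int) -> list[Mutation]:
        """All mutations carried by cells of a lineage (its full ancestry)."""
        ids = set()
        for anc in self.ancestry(lineage_id):
            ids.update(self.lineages[anc].mutation_ids)
        by_id = {m.id: m for m in self.mutations}
        return [by_id[i] for i in sorted(ids)]

    def mutation_frequency(self, mutation_id: str) -> np.ndarray:
        """Per-generation cell frequency of a mutation (clade frequency of
        the lineage it founded)."""
        m = next(mu for mu in self.mutations if mu.id == mutation_id)
        return self.clade_freq[m.lineage]

    def truth_table(self) -> pd.DataFrame:
        """Tab-separated-friendly truth: one row per mutation."""
        rows = []
        for m in self.mutations:
            rows.append({
                "mutation_id": m.id, "lineage": m.lineage, "origin": m.origin,
                "chromosome": m.chromosome, "position": m.position,
                "ref": m.ref, "alt": m.alt, "class": m.mutation_class,
                "gene": m.gene, "zygosity": m.zygosity, "s": m.s,
            })
        return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def _draw_mutation(rng: np.random.Generator, genome: GenomeAnnotation,
                   mclass: str, mid: str, lineage: int, origin: int,
                   zygosity: str, s: float) -> Mutation:
    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), p=lens / lens.sum())
    chrom = chroms[ci]
    pos = int(rng.integers(1, genome.chrom_lengths[chrom] + 1))
    if mclass == "SNP":
        ref, alt = rng.choice(_BASES, size=2, replace=False)
    else:
        ref = str(rng.choice(_BASES))
        ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        ref, alt = (ref, ref + ins) if rng.random() < 0.5 else (ref + ins, ref)
    gene = genome.gene_at(chrom, pos) or ""
    return Mutation(id=mid, lineage=lineage, origin=origin, chromosome=chrom,
                    position=pos, ref=str(ref), alt=str(alt),
                    mutation_class=mclass, gene=gene, zygosity=zygosity, s=s)


def simulate_evolution(config: SimConfig,
                       genome: GenomeAnnotation | None = None) -> LineageForest:
    """Run the Wright-Fisher lineage simulation.

    Returns a :class:`LineageForest` whose ``genotype_freq`` rows sum to one
    at every generation (exact genotype classes) and whose per-lineage
    ``frequency`` series are clade frequencies.
    """
    genome = genome or synthetic_genome()
    rng = np.random.default_rng(config.seed)
    N = max(1, int(round(config.population_size * (1.0 - config.death_rate))))
    n_gen = config.n_generations
    # tolerance mutations are worth more as the ethanol ramp rises:
    # s_eff = s * stress(t) / stress(0)
    stress_ref = config.stress_schedule[0][1] or 1.0

    founder = TrueLineage(id=0, parent=None, origin=0, mutation_ids=[],
                          s=0.0, ploidy=1, mutator_fold={})
    lineages = [founder]
    mutations: list[Mutation] = []
    counts = np.array([N], dtype=np.int64)
    freq_hist = [counts / N]
    planted_lineage_id: dict[int, int] = {-1: 0}

    class_rates = {
        "SNP": (config.beneficial_rate + config.neutral_rate) * config.snp_fraction,
        "indel": (config.beneficial_rate + config.neutral_rate) * (1 - config.snp_fraction),
    }
    p_beneficial = (config.beneficial_rate /
                    (config.beneficial_rate + config.neutral_rate)
                    if config.beneficial_rate + config.neutral_rate > 0 else 0.0)

    def spawn(parent: int, gen: int, s: float, ploidy: int | None = None,
              mutator_fold: dict[str, float] | None = None,
              mut: Mutation | None = None) -> None:
        par = lineages[parent]
        lin = TrueLineage(
            id=len(lineages), parent=parent, origin=gen,
            mutation_ids=[mut.id] if mut is not None else [],
            s=par.s + s,
            ploidy=ploidy if ploidy is not None else par.ploidy,
            mutator_fold=dict(mutator_fold if mutator_fold is not None
                              else par.mutator_fold))
        if mut is not None:
            mut.lineage = lin.id
        lineages.append(lin)

    for gen in range(1, n_gen + 1):
        stress = config.stress_at(gen) / stress_ref
        s_arr = np.array([l.s for l in lineages])
        w = np.exp(s_arr * stress)  # Malthusian fitness: odds grow as e^{s t}
        p = counts * w
        p = p / p.sum()
        counts = rng.multinomial(N, p)

        # planted lineages with known truth: transfer f0 of the parent clade
        for pi, pl in enumerate(config.planted):
            if gen != pl.onset:
                continue
            parent = planted_lineage_id.get(pl.parent, 0)
            take = min(counts[parent], max(1, int(round(pl.f0 * N))))
            if counts[parent] < 1:
                continue
            muts = []
            for _ in range(pl.n_mutations):
                mut = _draw_mutation(rng, genome, pl.mutation_class,
                                     f"m{len(mutations):05d}", -1, gen,
                                     pl.zygosity, pl.s)
                mutations.append(mut)
                muts.append(mut)
            spawn(parent, gen, pl.s, mut=muts[0] if muts else None)
            if len(muts) > 1:
                lineages[-1].mutation_ids.extend(m.id for m in muts[1:])
                for m in muts[1:]:
                    m.lineage = lineages[-1].id
            planted_lineage_id[pi] = lineages[-1].id
            counts = np.append(counts, take)
            counts[parent] -= take

        # scheduled events take over the currently most frequent lineage
        # (the mutator/ploidy background is treated as established)
        if config.ploidy_event and gen == config.ploidy_event.onset:
            parent = int(np.argmax(counts))
            if counts[parent] > 0:
                spawn(parent, gen, config.ploidy_event.advantage, ploidy=2)
                counts = np.append(counts, counts[parent])
                counts[parent] = 0
        if config.mutator_spec and gen == config.mutator_spec.onset:
            parent = int(np.argmax(counts[:len(lineages)]))
            if counts[parent] > 0:
                folds = dict(lineages[parent].mutator_fold)
                folds[config.mutator_spec.mutation_class] = (
                    folds.get(config.mutator_spec.mutation_class, 1.0)
                    * config.mutator_spec.fold)
                spawn(parent, gen, 0.0, mutator_fold=folds)
                counts = np.append(counts, counts[parent])
                counts[parent] = 0

        # new mutations on existing backgrounds, supply proportional to counts
        n_before = len(lineages)
        for mclass, base_rate in class_rates.items():
            if base_rate <= 0:
                continue
            folds = np.array([l.mutator_fold.get(mclass, 1.0)
                              for l in lineages[:n_before]])
            lam = counts[:n_before] * base_rate * folds
            n_new = rng.poisson(lam)
            for li in np.flatnonzero(n_new):
                for _ in range(int(n_new[li])):
                    if counts[li] < 1:
                        break
                    beneficial = rng.random() < p_beneficial
                    s = float(rng.exponential(config.dfe_mean)) if beneficial else 0.0
                    zyg = ("heterozygous" if lineages[li].ploidy > 1
                           else "homozygous")
                    mut = _draw_mutation(rng, genome, mclass,
                                         f"m{len(mutations):05d}", -1, gen, zyg, s)
                    mutations.append(mut)
                    spawn(li, gen, s, mut=mut)
                    counts = np.append(counts, 1)
                    counts[li] -= 1
        freq_hist.append(counts / N)

    n_lin = len(lineages)
    geno = np.zeros((n_lin, n_gen + 1))
    for t, f in enumerate(freq_hist):
        geno[:len(f), t] = f
    return LineageForest(lineages, mutations, geno, config, genome)


@dataclass
class ObservedDataset:
    """Observations shaped like the study's sequencing output."""
    trajectories: pd.DataFrame          # variant trajectory table
    clone_genotypes: pd.DataFrame       # long: clone x mutation zygosity
    depth_tracks: dict[str, pd.DataFrame]  # clone id -> binned counts
    clone_lineage: dict[str, int]       # clone id -> true lineage
    truth: LineageForest


def _allele_frequency(forest: LineageForest, m: Mutation) -> np.ndarray:
    """Sequencing-visible allele frequency: heterozygous-on-diploid mutations
    show half their cell frequency."""
    cell = forest.clade_freq[m.lineage]
    if m.zygosity == "heterozygous":
        return cell * 0.5
    return cell


def observe_sequencing(forest: LineageForest, config: SimConfig | None = None,
                       rng: np.random.Generator | None = None) -> ObservedDataset:
    """Generate the observed dataset: noisy population trajectories, clone
    genotypes and per-clone binned depth tracks with planted CNVs."""
    config = config or forest.config
    if config.population_coverage <= 0 or config.clone_coverage <= 0:
        raise ValueError("coverage must be > 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gens = list(config.sample_generations)

    rows = []
    for m in forest.mutations:
        af = _allele_frequency(forest, m)
        row = {"mutation_id": m.id, "chromosome": m.chromosome,
               "position": m.position, "ref": m.ref, "alt": m.alt,
               "class": m.mutation_class, "gene": m.gene}
        for g in gens:
            depth = rng.poisson(config.population_coverage)
            if depth == 0:
                row[f"g{g}"] = np.nan
            else:
                row[f"g{g}"] = rng.binomial(depth, min(1.0, af[g])) / depth
        rows.append(row)
    traj = pd.DataFrame(rows, columns=["mutation_id", "chromosome", "position",
                                       "ref", "alt", "class", "gene"]
                        + [f"g{g}" for g in gens])

    clone_rows = []
    clone_lineage: dict[str, int] = {}
    depth_tracks: dict[str, pd.DataFrame] = {}
    for g in gens:
        f = forest.genotype_freq[:, g]
        alive = np.flatnonzero(f > 0)
        k = min(config.clones_per_timepoint, len(alive))
        picked = rng.choice(alive, size=k, replace=False, p=f[alive] / f[alive].sum())
        if k < config.clones_per_timepoint:  # fewer distinct backgrounds than colonies
            extra = rng.choice(alive, size=config.clones_per_timepoint - k,
                               replace=True, p=f[alive] / f[alive].sum())
            picked = np.concatenate([picked, extra])
        for ci, li in enumerate(picked):
            clone_id = f"g{g}_c{ci}"
            clone_lineage[clone_id] = int(li)
            for m in forest.mutations_of(int(li)):
                clone_rows.append({"clone": clone_id, "generation": g,
                                   "mutation_id": m.id, "zygosity": m.zygosity})
            depth_tracks[clone_id] = simulate_depth_track(
                forest.genome, config.clone_coverage, config.bin_size,
                cnv_events=[e for e in config.cnv_events
                            if e.carrier_lineage is None
                            or e.carrier_lineage in forest.ancestry(int(li))],
                rng=rng, baseline_ploidy=config.baseline_ploidy)
    clone_genotypes = pd.DataFrame(
        clone_rows, columns=["clone", "generation", "mutation_id", "zygosity"])
    return ObservedDataset(trajectories=traj, clone_genotypes=clone_genotypes,
                           depth_tracks=depth_tracks, clone_lineage=clone_lineage,
                           truth=forest)


def true_trajectory_table(forest: LineageForest,
                          allele: bool = False) -> pd.DataFrame:
    """Noiseless trajectory table at the sample generations: cell-level
    frequencies by default, sequencing-visible allele frequencies (het
    halved) when ``allele``."""
    gens = list(forest.config.sample_generations)
    rows = []
    for m in forest.mutations:
        f = _allele_frequency(forest, m) if allele else forest.clade_freq[m.lineage]
        row = {"mutation_id": m.id, "chromosome": m.chromosome,
               "position": m.position, "ref": m.ref, "alt": m.alt,
               "class": m.mutation_class, "gene": m.gene}
        for g in gens:
            row[f"g{g}"] = f[g]
        rows.append(row)
    return pd.DataFrame(rows, columns=["mutation_id", "chromosome", "position",
                                       "ref", "alt", "class", "gene"]
                        + [f"g{g}" for g in gens])


def simulate_depth_track(genome: GenomeAnnotation, coverage: float = 80.0,
                         bin_size: int = 500,
                         cnv_events: list[CNVEvent] | None = None,
                         rng: np.random.Generator | None = None,
                         baseline_ploidy: int = 2,
                         seed: int | None = None) -> pd.DataFrame:
    """Binned read counts for one clone: Poisson with mean
    ``coverage * bin_size / read_length * copy / baseline_ploidy`` per bin."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean_reads = coverage * bin_size / _READ_LENGTH_PROXY
    frames = []
    for chrom, length in genome.chrom_lengths.items():
        starts = np.arange(0, length - bin_size + 1, bin_size)
        mean = np.full(len(starts), mean_reads)
        for ev in cnv_events or []:
            if ev.chromosome != chrom:
                continue
            sel = (starts >= ev.start) & (starts < ev.end)
            mean[sel] *= ev.copy_number / baseline_ploidy
        frames.append(pd.DataFrame({
            "chromosome": chrom, "start": starts, "end": starts + bin_size,
            "count": rng.poisson(mean)}))
    return pd.concat(frames, ignore_index=True)


def simulate_competition(s_true: float, T: int, noise_sd: float = 0.0,
                         seed: int | None = None, n0: float = 1e6,
                         n_points: int | None = None):
    """Exponential two-strain competition with a fluorescent reference.

    The log count ratio follows ln(U/R)(t) = ln(U0/R0) + s*t plus Gaussian
    measurement noise. Returns ``(record, series)`` where ``record`` is a
    :class:`evotrace.fitness.CompetitionRecord` holding endpoint counts
    consistent with the series and ``series`` is a DataFrame of the ln-ratio
    time course.
    """
    from .fitness import CompetitionRecord
    if T < 1:
        raise ValueError("T must be >= 1")
    if n0 <= 0:
        raise ValueError("initial counts must be positive")
    rng = np.random.default_rng(seed)
    ts = np.arange(T + 1) if n_points is None else np.linspace(0, T, n_points)
    lr = s_true * ts + rng.normal(0.0, noise_sd, size=len(ts))
    lr[0] = 0.0  # equal inoculum measured without error by construction
    series = pd.DataFrame({"generation": ts, "ln_ratio": lr})
    record = CompetitionRecord(U_i=n0, R_i=n0, U_f=n0 * math.exp(lr[-1]),
                               R_f=n0, T=float(T))
    return record, series


def simulate_fluorescence(s_true: float, T: float = 28.0, noise_sd: float = 0.02,
                          orientation: str = "mutant-in-channel-1",
                          n_points: int = 8, seed: int | None = None,
                          control_slope: float = 0.0,
                          background: tuple[float, float] = (50.0, 40.0),
                          replicate: str = "r1"):
    """One two-colour fluorescence competition series with the mutant's
    signal growing at rate ``s_true`` relative to the reference (plus any
    marker-specific ``control_slope``), read out as background-inflated
    channel intensities."""
    from .fitness import FluorescenceSeries
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, T, n_points)
    lr = (s_true + control_slope) * ts + rng.normal(0.0, noise_sd, len(ts))
    ref = 1000.0 * np.ones(len(ts))
    mut = ref * np.exp(lr)
    b1, b2 = background
    if orientation == "mutant-in-channel-1":
        ch1, ch2 = mut + b1, ref + b2
    else:
        ch1, ch2 = ref + b1, mut + b2
    return FluorescenceSeries(
        generations=ts, channel1=ch1, channel2=ch2,
        background1=b1, background2=b2, orientation=orientation,
        replicate=replicate)
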