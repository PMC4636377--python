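"""Study-calibrated simulation presets.

These bundle the simulator configurations used throughout the package's
validation: the default evolution-experiment calibration (200 generations
under a stepped ethanol ramp, 500x population / 80x clone coverage, three
clones per time point), a mutator-reactor variant, and planted-truth
scenarios for cohort clustering, Muller nesting and CNV calling.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeAnnotation, synthetic_genome
from .simulate import (CNVEvent, MutatorSpec, PlantedLineage, SimConfig,
                       default_stress_schedule)

__all__ = ["study_preset", "mutator_reactor_preset", "planted_cohort_preset",
           "planted_cnv_events", "noisy_observation"]


def study_preset(seed: int = 0, **overrides) -> SimConfig:
    """Default calibration mimicking the study: 200 generations, sequencing
    time points spread over the ramp, 500x/80x coverage, 3 clones per time
    point."""
    kw = dict(
        population_size=100_000,
        n_generations=200,
        sample_generations=[0, 40, 80, 120, 160, 200],
        population_coverage=500.0,
        clone_coverage=80.0,
        clones_per_timepoint=3,
        stress_schedule=default_stress_schedule(200),
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def mutator_reactor_preset(seed: int = 0, **overrides) -> SimConfig:
    """Reactor-2-like run: an indel mutator arises around generation 80 and
    hitch-hikes with the sweeping background."""
    kw = dict(mutator_spec=MutatorSpec(onset=80, fold=50,
                                       mutation_class="indel"),
              # lower base supply keeps the mutator's lineage count tractable
              beneficial_rate=1e-5, neutral_rate=2e-5)
    kw.update(overrides)
    return study_preset(seed, **kw)


def planted_cohort_preset(seed: int = 0, noise: bool = False) -> SimConfig:
    """Four planted mutation cohorts with known linkage and parentage:
    C2 arises on C1's background, C3 on C2's, C4 sweeps independently."""
    return SimConfig(
        population_size=1_000_000,
        n_generations=120,
        sample_generations=[0, 20, 40, 60, 80, 100, 120],
        beneficial_rate=0.0, neutral_rate=0.0,
        stress_schedule=[(0, 1.0)],
        planted=[
            PlantedLineage(onset=10, s=0.10, f0=0.02, parent=-1, n_mutations=3),
            PlantedLineage(onset=40, s=0.05, f0=0.05, parent=0, n_mutations=2),
            PlantedLineage(onset=70, s=0.05, f0=0.05, parent=1, n_mutations=2),
            PlantedLineage(onset=20, s=0.02, f0=0.10, parent=-1, n_mutations=2),
        ],
        seed=seed)


def planted_cnv_events(genome: GenomeAnnotation | None = None,
                       n_bins: int = 100) -> tuple[GenomeAnnotation, list[CNVEvent]]:
    """A focal trisomic segment of ``n_bins`` 500-bp bins on chr02 plus a
    hemizygous loss of the same size on chr03, on a diploid background."""
    genome = genome or synthetic_genome()
    span = n_bins * 500
    events = [
        CNVEvent(chromosome="chr02", start=100_000, end=100_000 + span,
                 copy_number=3),
        CNVEvent(chromosome="chr03", start=150_000, end=150_000 + span,
                 copy_number=1),
    ]
    return genome, events


def noisy_observation(true_freqs: np.ndarray, depth: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Binomial sequencing noise at the given mean depth (Poisson per site)."""
    depths = np.maximum(1, rng.poisson(depth, size=true_freqs.shape))
    return rng.binomial(depths, np.clip(true_freqs, 0, 1)) / depths
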