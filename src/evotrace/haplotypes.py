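"""Haplotype-cohort reconstruction and Muller-diagram nesting.

Mutations whose population frequencies move together through time are
inferred to be linked on one background ("cohorts"). Cohorts come from
agglomerative complete-linkage clustering on the Euclidean distance between
trajectories; cohort frequency is the arithmetic mean of its members; the
Muller nesting forest is inferred by frequency containment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .variants import freq_columns

__all__ = [
    "TrajectoryMatrix", "Cohort", "MullerDiagram",
    "cluster_trajectories", "clonal_interference_stats",
    "build_muller", "export_muller", "load_muller",
]


@dataclass
class TrajectoryMatrix:
    """Complete frequency matrix: rows = mutations, columns = generations."""
    mutation_ids: list[str]
    generations: list[int]
    frequencies: np.ndarray  # (n_mutations, n_generations)
    reactor: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(self.mutation_ids), len(self.generations)):
            raise ValueError("frequency matrix shape mismatch")
        if list(self.generations) != sorted(set(self.generations)):
            raise ValueError("generations must be strictly increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, reactor: str = "",
                   interpolate: bool = True) -> "TrajectoryMatrix":
        """Build from a trajectory table; missing interior time points are
        linearly interpolated, leading missing values set to 0."""
        cols = freq_columns(table)
        gens = [int(c[1:]) for c in cols]
        f = table[cols].to_numpy(dtype=float)
        if interpolate and np.isnan(f).any():
            f = (pd.DataFrame(f).interpolate(axis=1, limit_direction="forward")
                 .fillna(0.0).to_numpy())
        return cls(mutation_ids=list(table["mutation_id"].astype(str)),
                   generations=gens, frequencies=f, reactor=reactor)


@dataclass
class Cohort:
    """A group of linked mutations moving together through time."""
    label: str
    members: list[str]
    generations: list[int]
    mean_trajectory: np.ndarray

    @property
    def origin(self) -> int:
        """First observed generation with mean frequency > 0."""
        nz = np.flatnonzero(self.mean_trajectory > 0)
        return int(self.generations[nz[0]]) if len(nz) else int(self.generations[-1])


def cluster_trajectories(matrix: TrajectoryMatrix,
                         distance_threshold: float = 0.3) -> list[Cohort]:
    """Complete-linkage agglomerative clustering on Euclidean trajectory
    distance, cut at ``distance_threshold``; all within-cohort pairwise
    distances are therefore <= threshold."""
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be > 0")
    if np.isnan(matrix.frequencies).any():
        raise ValueError("trajectory matrix must be complete (impute first)")
    n = len(matrix.mutation_ids)
    # stable row order: sort by mutation id so merges tie-break reproducibly
    order = sorted(range(n), key=lambda i: matrix.mutation_ids[i])
    f = matrix.frequencies[order]
    ids = [matrix.mutation_ids[i] for i in order]
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(f, metric="euclidean"), method="complete")
        labels = fcluster(z, t=distance_threshold, criterion="distance")
    cohorts = []
    for lab in np.unique(labels):
        sel = np.flatnonzero(labels == lab)
        members = sorted(ids[i] for i in sel)
        cohorts.append(Cohort(label="", members=members,
                              generations=list(matrix.generations),
                              mean_trajectory=f[sel].mean(axis=0)))
    cohorts.sort(key=lambda c: (c.origin, c.members[0]))
    for i, c in enumerate(cohorts):
        c.label = f"C{i + 1:02d}"
    return cohorts


def clonal_interference_stats(matrix: TrajectoryMatrix,
                              drop_threshold: float = 0.10) -> pd.DataFrame:
    """Flag extinct mutations and decliners.

    extinct: observed > 0 at some generation and exactly 0 at the final
    observed generation. decliner: some later observation sits more than
    ``drop_threshold`` (strict) below the running maximum — i.e. the
    mutation dropped after reaching its maximum frequency.
    """
    f = matrix.frequencies
    running_max = np.maximum.accumulate(f, axis=1)
    drop = running_max[:, :-1] - f[:, 1:]
    decliner = (drop > drop_threshold).any(axis=1) if f.shape[1] > 1 else \
        np.zeros(len(f), dtype=bool)
    extinct = (f.max(axis=1) > 0) & (f[:, -1] == 0)
    return pd.DataFrame({"mutation_id": matrix.mutation_ids,
                         "max_frequency": f.max(axis=1),
                         "final_frequency": f[:, -1],
                         "extinct": extinct, "decliner": decliner})


@dataclass
class MullerDiagram:
    """Nesting forest over cohorts plus per-generation frequencies."""
    cohorts: list[Cohort]
    parents: dict[str, str | None]            # cohort label -> parent label
    generations: list[int]
    residual: np.ndarray                      # ancestral fraction per generation
    warnings: list[str] = field(default_factory=list)

    def children(self, label: str | None) -> list[str]:
        return sorted(k for k, v in self.parents.items() if v == label)


def build_muller(cohorts: list[Cohort], epsilon: float = 0.02) -> MullerDiagram:
    """Infer nesting by containment: B nests in A when A arose earlier and
    freq_B(t) <= freq_A(t) + epsilon wherever B is present; among eligible
    parents the tightest (smallest mean frequency excess) wins."""
    if not cohorts:
        return MullerDiagram([], {}, [], np.zeros(0))
    gens = cohorts[0].generations
    parents: dict[str, str | None] = {}
    warnings: list[str] = []
    by_label = {c.label: c for c in cohorts}
    for c in cohorts:
        present = c.mean_trajectory > 0
        best, best_excess = None, np.inf
        violated = False
        for cand in cohorts:
            if cand.label == c.label or cand.origin >= c.origin:
                continue
            diff = cand.mean_trajectory[present] - c.mean_trajectory[present]
            if (diff >= -epsilon).all():
                excess = diff.mean()
                if excess < best_excess:
                    best, best_excess = cand.label, excess
            else:
                violated = True
        parents[c.label] = best
        if best is None and violated:
            warnings.append(f"{c.label}: containment violated for all "
                            f"candidate parents; placed top-level")
    top = [by_label[k].mean_trajectory for k, v in parents.items() if v is None]
    residual = 1.0 - (np.sum(top, axis=0) if top else np.zeros(len(gens)))
    return MullerDiagram(cohorts=cohorts, parents=parents,
                         generations=list(gens), residual=residual,
                         warnings=warnings)


def export_muller(diagram: MullerDiagram, json_path: str | None = None,
                  tsv_path: str | None = None) -> dict:
    """Serialise to a JSON document and a long-format frequency table."""
    doc = {
        "generations": list(map(int, diagram.generations)),
        "residual_ancestral": [float(x) for x in diagram.residual],
        "cohorts": [{
            "label": c.label,
            "members": list(c.members),
            "parent": diagram.parents.get(c.label),
            "origin": c.origin,
            "frequency": [float(x) for x in c.mean_trajectory],
        } for c in diagram.cohorts],
    }
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1)
    if tsv_path:
        rows = [{"cohort": c["label"], "parent": c["parent"] or "",
                 "generation": g, "frequency": f}
                for c in doc["cohorts"]
                for g, f in zip(doc["generations"], c["frequency"])]
        pd.DataFrame(rows, columns=["cohort", "parent", "generation",
                                    "frequency"]).to_csv(tsv_path, sep="\t",
                                                         index=False)
    return doc


def load_muller(json_path: str) -> MullerDiagram:
    with open(json_path) as fh:
        doc = json.load(fh)
    cohorts = [Cohort(label=c["label"], members=list(c["members"]),
                      generations=list(doc["generations"]),
                      mean_trajectory=np.asarray(c["frequency"]))
               for c in doc["cohorts"]]
    parents = {c["label"]: c["parent"] for c in doc["cohorts"]}
    return MullerDiagram(cohorts=cohorts, parents=parents,
                         generations=list(doc["generations"]),
                         residual=np.asarray(doc["residual_ancestral"]))
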