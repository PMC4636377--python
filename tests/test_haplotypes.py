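"""Cohort clustering, clonal-interference flags and Muller nesting."""

import itertools

import numpy as np
import pytest

from evotrace.haplotypes import (Cohort, MullerDiagram, TrajectoryMatrix,
                                 build_muller, clonal_interference_stats,
                                 cluster_trajectories, export_muller,
                                 load_muller)
from evotrace.simulate import (PlantedLineage, SimConfig, simulate_evolution,
                               true_trajectory_table)


def matrix(rows: dict[str, list[float]], gens=None) -> TrajectoryMatrix:
    gens = gens or list(range(len(next(iter(rows.values())))))
    return TrajectoryMatrix(mutation_ids=list(rows),
                            generations=gens,
                            frequencies=np.array(list(rows.values()), float))


def partitions(items):
    """All set partitions (Bell number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_feasible_partition(f: np.ndarray, threshold: float):
    """Oracle: among partitions whose blocks all have max pairwise Euclidean
    distance <= threshold, the one with fewest blocks (tie-break: smallest
    total within-block distance)."""
    n = len(f)
    d = np.linalg.norm(f[:, None, :] - f[None, :, :], axis=2)
    best, best_key = None, None
    for part in partitions(range(n)):
        ok = all(d[i, j] <= threshold
                 for block in part for i, j in itertools.combinations(block, 2))
        if not ok:
            continue
        tot = sum(d[i, j] for block in part
                  for i, j in itertools.combinations(block, 2))
        key = (len(part), tot)
        if best_key is None or key < best_key:
            best, best_key = part, key
    return {frozenset(block) for block in best}


class TestClustering:
    def test_identical_trajectories_merge(self):
        m = matrix({"a": [0, 0.5, 1.0], "b": [0, 0.5, 1.0]})
        cohorts = cluster_trajectories(m, 0.01)
        assert len(cohorts) == 1 and cohorts[0].members == ["a", "b"]

    def test_distant_trajectories_split(self):
        m = matrix({"a": [0, 0, 1.0], "b": [1.0, 0, 0]})
        cohorts = cluster_trajectories(m, 0.5)
        assert len(cohorts) == 2

    def test_single_row_is_singleton(self):
        m = matrix({"a": [0, 0.4, 0.9]})
        cohorts = cluster_trajectories(m, 0.3)
        assert len(cohorts) == 1 and cohorts[0].members == ["a"]

    def test_mean_trajectory_is_member_average(self):
        m = matrix({"a": [0, 0.4, 1.0], "b": [0, 0.5, 0.9]})
        c = cluster_trajectories(m, 0.5)[0]
        assert np.allclose(c.mean_trajectory, [0, 0.45, 0.95])

    def test_recovers_planted_cohorts_against_exhaustive_oracle(self):
        """Two planted cohorts of three mutations each, read at 500x binomial
        noise: the clustering equals the best feasible partition found by
        exhaustive enumeration over all 203 partitions of 6 rows, which in
        turn equals the planted partition."""
        rng = np.random.default_rng(12)
        base1 = np.array([0.0, 0.1, 0.45, 0.9])
        base2 = np.array([0.0, 0.6, 0.3, 0.05])
        depth = 500
        rows = {}
        for i in range(3):
            rows[f"a{i}"] = rng.binomial(depth, base1) / depth
        for i in range(3):
            rows[f"b{i}"] = rng.binomial(depth, base2) / depth
        m = matrix(rows)
        threshold = 0.3
        cohorts = cluster_trajectories(m, threshold)
        got = {frozenset(c.members) for c in cohorts}
        planted = {frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}
        ids = list(rows)
        oracle = best_feasible_partition(np.array(list(rows.values())), threshold)
        oracle = {frozenset(ids[i] for i in block) for block in oracle}
        assert got == planted == oracle

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = {f"m{i}": rng.random(4) for i in range(8)}
        m1 = matrix(rows)
        shuffled = dict(reversed(list(rows.items())))
        m2 = matrix(shuffled)
        p1 = {frozenset(c.members) for c in cluster_trajectories(m1, 0.4)}
        p2 = {frozenset(c.members) for c in cluster_trajectories(m2, 0.4)}
        assert p1 == p2

    def test_rejects_incomplete_matrix(self):
        m = matrix({"a": [0, 0.5, 1.0], "b": [0, 0.5, 1.0]})
        m.frequencies[0, 1] = np.nan
        with pytest.raises(ValueError):
            cluster_trajectories(m, 0.3)

    def test_cohort_means_in_unit_interval(self):
        rng = np.random.default_rng(3)
        m = matrix({f"m{i}": rng.random(5) for i in range(10)})
        for c in cluster_trajectories(m, 0.6):
            assert ((c.mean_trajectory >= 0) & (c.mean_trajectory <= 1)).all()


class TestInterferenceStats:
    @pytest.mark.parametrize("traj,extinct,decliner", [
        ([0.2, 0.5, 0.35], False, True),   # drop 0.15 from max
        ([0.3, 0.1, 0.0], True, True),
        ([0.0, 0.2, 1.0], False, False),   # monotone rise
        ([0.0, 0.05, 0.0], True, False),   # extinct but small drop
    ])
    def test_flag_rules(self, traj, extinct, decliner):
        stats = clonal_interference_stats(matrix({"m": traj}))
        assert bool(stats.iloc[0]["extinct"]) is extinct
        assert bool(stats.iloc[0]["decliner"]) is decliner

    def test_matches_truth_flags_on_noiseless_simulation(self):
        cfg = SimConfig(seed=21, n_generations=150,
                        sample_generations=[0, 50, 100, 150])
        forest = simulate_evolution(cfg)
        table = true_trajectory_table(forest)
        m = TrajectoryMatrix.from_table(table)
        stats = clonal_interference_stats(m)
        gens = [0, 50, 100, 150]
        for _, row in stats.iterrows():
            truth = forest.mutation_frequency(row["mutation_id"])[gens]
            assert bool(row["extinct"]) == bool(truth.max() > 0 and truth[-1] == 0)
            run_max = np.maximum.accumulate(truth)
            assert bool(row["decliner"]) == bool(
                (run_max[:-1] - truth[1:] > 0.10).any())


def planted_nested_forest(seed=2):
    """Four planted cohorts with known parentage: C2 inside C1, C3 inside C2,
    C4 an independent top-level sweep."""
    cfg = SimConfig(
        population_size=1_000_000, n_generations=120,
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
    return simulate_evolution(cfg)


class TestMuller:
    def test_forced_containment_nests(self):
        c1 = Cohort("C1", ["a"], [0, 50, 100], np.array([0.0, 0.4, 1.0]))
        c2 = Cohort("C2", ["b"], [0, 50, 100], np.array([0.0, 0.0, 0.6]))
        d = build_muller([c1, c2])
        assert d.parents == {"C1": None, "C2": "C1"}

    def test_crossing_sweeps_stay_top_level(self):
        # each exceeds the other at some generation: no containment
        c1 = Cohort("C1", ["a"], [0, 50, 100], np.array([0.0, 0.4, 0.3]))
        c2 = Cohort("C2", ["b"], [0, 50, 100], np.array([0.0, 0.0, 0.6]))
        d = build_muller([c1, c2])
        assert d.parents["C2"] is None
        assert d.warnings  # containment violated for all candidates
        assert (d.residual >= -0.02).all()

    def test_planted_parentage_recovered_from_noiseless_truth(self):
        forest = planted_nested_forest()
        table = true_trajectory_table(forest)
        m = TrajectoryMatrix.from_table(table)
        cohorts = cluster_trajectories(m, 0.3)
        # cohorts recover the planted groups exactly
        planted = {}
        for lin in forest.lineages[1:]:
            planted[frozenset(lin.mutation_ids)] = lin
        assert {frozenset(c.members) for c in cohorts} == set(planted)
        diagram = build_muller(cohorts)
        label_of = {frozenset(c.members): c.label for c in cohorts}
        for group, lin in planted.items():
            parent_lin = forest.lineages[lin.parent]
            expected = (None if parent_lin.parent is None and not parent_lin.mutation_ids
                        else label_of[frozenset(parent_lin.mutation_ids)])
            assert diagram.parents[label_of[group]] == expected

    def test_residual_nonnegative_on_noiseless_truth(self):
        forest = planted_nested_forest(seed=5)
        table = true_trajectory_table(forest)
        cohorts = cluster_trajectories(TrajectoryMatrix.from_table(table), 0.3)
        d = build_muller(cohorts, epsilon=0.0)
        assert (d.residual >= -1e-9).all()

    def test_export_roundtrip(self, tmp_path):
        forest = planted_nested_forest()
        cohorts = cluster_trajectories(
            TrajectoryMatrix.from_table(true_trajectory_table(forest)), 0.3)
        d = build_muller(cohorts)
        path = tmp_path / "muller.json"
        export_muller(d, json_path=str(path), tsv_path=str(tmp_path / "m.tsv"))
        back = load_muller(str(path))
        assert back.parents == d.parents
        assert [c.members for c in back.cohorts] == [c.members for c in d.cohorts]
        assert np.allclose(back.residual, d.residual)

    def test_empty_diagram_exports(self, tmp_path):
        doc = export_muller(MullerDiagram([], {}, [], np.zeros(0)),
                            json_path=str(tmp_path / "e.json"))
        assert doc["cohorts"] == []
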