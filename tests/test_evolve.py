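"""Chimera scalarization, fitness evaluation, GA loop and Pareto fronts."""

import numpy as np
import pytest

from gencat.benchmark import TruthPerformanceModel, brute_force_optimum
from gencat.evolve import (
    FitnessVector,
    GAConfig,
    ScalarizerSpec,
    chimera_scalarize,
    evaluate_candidate,
    evolve,
    pareto_front,
)
from gencat.fragments import sample_random
from gencat.reactions import SubstratePanel

SPEC = ScalarizerSpec()


def ranking(matrix, spec=SPEC):
    m = chimera_scalarize(np.asarray(matrix, dtype=float), spec)
    return list(np.argsort(-m, kind="stable"))


def test_hard_selectivity_floor():
    # A meets the 2.0 kcal/mol floor, B does not; all else equal
    a = [2.1, 0.5, 0.1, 0.1]
    b = [1.6, 0.5, 0.1, 0.1]
    merits = chimera_scalarize(np.array([a, b]), SPEC)
    assert merits[0] > merits[1]


def test_hierarchy_breaks_ties_with_last_objective():
    # both satisfy every threshold and agree on objectives 1-3
    a = [2.5, 0.8, 0.05, 0.01]
    b = [2.5, 0.8, 0.05, 0.30]
    merits = chimera_scalarize(np.array([a, b]), SPEC)
    assert merits[0] > merits[1]


def test_nonfinite_rows_fall_to_worst_tier():
    rows = np.array([[2.5, 0.8, 0.05, 0.01], [np.nan, 0.9, 0.01, 0.01]])
    merits = chimera_scalarize(rows, SPEC)
    assert merits[1] == -1.0 and merits[0] > merits[1]


def test_scalarizer_invariant_to_candidate_ordering(rng):
    M = rng.random((30, 4)) * [4.0, 1.0, 1.0, 0.5]
    perm = rng.permutation(30)
    m1 = chimera_scalarize(M, SPEC)
    m2 = chimera_scalarize(M[perm], SPEC)
    assert np.argsort(-m1).tolist() == perm[np.argsort(-m2)].tolist()


def test_scalarizer_ordering_invariant_to_affine_rescaling(rng):
    """Scaling an objective column and its absolute threshold identically
    leaves the ranking unchanged."""
    M = rng.random((25, 4)) * [4.0, 1.0, 1.0, 0.5]
    scaled = M.copy()
    scaled[:, 0] = 3.0 * scaled[:, 0]
    spec_scaled = ScalarizerSpec(ddg_floor=3.0 * SPEC.ddg_floor)
    assert ranking(M) == ranking(scaled, spec_scaled)


def lexicographic_ranking(M, floor=2.0):
    """Brute-force comparator for the zero-tolerance limit: candidates
    meeting the floor rank above the rest; within the top group order by
    objective 2 (max), then 3 (min), then 4 (min); below the floor order
    by objective 1."""
    def key(i):
        row = M[i]
        meets = row[0] >= floor
        return (
            0 if meets else 1,
            (-row[1], row[2], row[3]) if meets else (-row[0],),
        )

    return sorted(range(len(M)), key=key)


def test_zero_tolerance_limit_is_lexicographic(rng):
    spec0 = ScalarizerSpec(activity_degradation=1e-12, spread_tolerance=1e-12)
    for _ in range(200):
        M = np.column_stack([
            rng.uniform(0, 4, 12), rng.uniform(0, 1, 12),
            rng.uniform(0, 1, 12), rng.uniform(0, 0.5, 12),
        ])
        assert ranking(M, spec0) == lexicographic_ranking(M)


def test_evaluate_candidate_degenerate_panels(landscape):
    model = TruthPerformanceModel(landscape)
    cand = sample_random(landscape.library, 0)
    pair = (landscape.sub_a[0], landscape.sub_b[0])
    single = evaluate_candidate(cand, SubstratePanel((pair,)), model)
    assert single.std_ddg == 0.0
    assert single.median_ddg == pytest.approx(
        landscape.ddg_truth(cand, *pair), abs=1e-12
    )


def test_fitness_statistics_match_recomputation(landscape, panel, rng):
    model = TruthPerformanceModel(landscape)
    for seed in range(20):
        cand = sample_random(landscape.library, int(rng.integers(2**31)))
        fv = evaluate_candidate(cand, panel, model)
        assert fv.median_ddg == pytest.approx(np.median(fv.ddg), abs=1e-12)
        assert fv.median_activity == pytest.approx(np.median(fv.activity), abs=1e-12)
        assert fv.std_ddg == pytest.approx(np.std(fv.ddg), abs=1e-12)
        assert fv.std_activity == pytest.approx(np.std(fv.activity), abs=1e-12)


def test_invalid_candidate_gets_worst_merit(landscape, panel):
    class FailingModel:
        def predict_selectivity(self, smiles, panel):
            raise ValueError("featurization failure")

        predict_descriptor = predict_selectivity

    cand = sample_random(landscape.library, 0)
    fv = evaluate_candidate(cand, panel, FailingModel())
    assert not fv.valid
    merits = chimera_scalarize(fv.objective_row()[None, :], SPEC)
    assert merits[0] == -1.0


def test_evolution_fixed_point_without_mutation(landscape, panel):
    model = TruthPerformanceModel(landscape)
    config = GAConfig(population_size=6, generations=5, mutation_rate=0.0,
                      selection_rate=0.99, elitism=6, seed=3)
    traj = evolve(config, landscape.library, panel, model)
    first = {c.assembled_smiles for c in
             [v.candidate for v in traj[0].population]}
    last = {v.candidate.assembled_smiles for v in traj[-1].population}
    assert first == last


def test_elitism_keeps_best_competitive(landscape, panel):
    """Within every generation's own scalarization, the new best ranks at
    least as high as the carried-over previous best."""
    model = TruthPerformanceModel(landscape)
    traj = evolve(GAConfig(seed=11, generations=25), landscape.library, panel, model)
    for rec in traj[1:]:
        assert rec.best.merit >= rec.elite_merit - 1e-12


def test_ga_reproducible_for_fixed_seed(landscape, panel):
    model = TruthPerformanceModel(landscape)
    t1 = evolve(GAConfig(seed=9, generations=10), landscape.library, panel, model)
    t2 = evolve(GAConfig(seed=9, generations=10), landscape.library, panel, model)
    s1 = [r.best.candidate.assembled_smiles for r in t1]
    s2 = [r.best.candidate.assembled_smiles for r in t2]
    assert s1 == s2


def test_memoization_avoids_repeat_model_calls(landscape, panel):
    model = TruthPerformanceModel(landscape)
    evolve(GAConfig(seed=2, generations=15), landscape.library, panel, model)
    stats = evolve.last_cache_stats
    # each unique candidate costs one selectivity + one descriptor call
    assert model.call_count == 2 * stats["misses"]
    assert stats["hits"] > 0


def test_ga_finds_brute_force_optimum_in_most_seeds(landscape, panel):
    best, _ = brute_force_optimum(landscape, panel)
    model = TruthPerformanceModel(landscape)
    wins = 0
    for seed in range(30):
        traj = evolve(GAConfig(seed=seed), landscape.library, panel, model)
        wins += traj[-1].best.candidate.assembled_smiles == best.assembled_smiles
    assert wins >= 27


def test_pareto_examples():
    pts = np.array([[1, 3], [2, 2], [3, 1], [1, 1]])
    assert pareto_front(pts, ("max", "max")) == [0, 1, 2]
    assert pareto_front(np.array([[5.0, 5.0]]), ("max", "max")) == [0]
    # under (max, min), (2, 2) dominates (1, 3)
    assert pareto_front(np.array([[1, 3], [2, 2]]), ("max", "min")) == [1]


def test_pareto_matches_quadratic_scan(rng):
    def scan(P):
        out = []
        for i in range(len(P)):
            dominated = False
            for j in range(len(P)):
                if (P[j] >= P[i]).all() and (P[j] > P[i]).any():
                    dominated = True
                    break
            if not dominated:
                out.append(i)
        return out

    for _ in range(500):
        P = rng.random((rng.integers(1, 40), 2))
        assert pareto_front(P, ("max", "max")) == scan(P)
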