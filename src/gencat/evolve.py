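"""Genetic optimization of catalyst generality over a substrate panel.

Each candidate catalyst is scored on every reaction of a fixed substrate
panel (the generality probing set) by two surrogate models — predicted
enantioselectivity ddG and predicted activity descriptor — and summarized
into four objectives:

  1. median ddG over the panel           (hard floor: >= 2.0 kcal/mol)
  2. median Gaussian activity merit f    (maximize, 10% degradation)
  3. spread (std) of ddG                 (minimize, 25% compromise)
  4. spread (std) of f                   (minimize, 25% compromise)

The objectives are reduced to a single merit by a Chimera-style hierarchical
achievement scalarization: the feasible region is carved objective by
objective (an absolute threshold for the first, best +/- fraction of the
population range for the rest), candidates are tiered by how many leading
thresholds they satisfy, and ranked within a tier by the first unsatisfied
objective.  The GA itself is a standard elitist loop: truncation selection,
uniform per-slot crossover, per-gene mutation within the fragment category.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .fragments import (
    AssemblyError,
    CatalystCandidate,
    FragmentLibrary,
    assemble,
    sample_random,
)
from .reactions import SubstratePanel
from .volcano import gaussian_activity

TOLUENE = "Cc1ccccc1"
BENZOIC_ACID = "OC(=O)c1ccccc1"
ACETIC_ACID = "CC(=O)O"


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 10
    generations: int = 50
    mutation_rate: float = 0.10
    selection_rate: float = 0.25
    elitism: int = 1
    seed: int = 0
    solvent: str = "toluene"
    cocatalyst_selectivity: str | None = BENZOIC_ACID
    cocatalyst_descriptor: str | None = ACETIC_ACID

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must have at least 2 individuals")
        for name in ("mutation_rate", "selection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class ScalarizerSpec:
    """The four hierarchical objectives and their thresholds."""

    ddg_floor: float = 2.0          # kcal/mol, absolute threshold on objective 1
    activity_degradation: float = 0.10
    spread_tolerance: float = 0.25
    activity_target: float = -9.0   # volcano peak descriptor, kcal/mol
    activity_width: float = 3.0     # kcal/mol

    #: (mode, fraction) per objective; mode in {threshold, maximize, minimize}
    @property
    def objectives(self) -> tuple[tuple[str, float], ...]:
        return (
            ("threshold", self.ddg_floor),
            ("maximize", self.activity_degradation),
            ("minimize", self.spread_tolerance),
            ("minimize", self.spread_tolerance),
        )


@dataclass
class FitnessVector:
    """Panel-resolved predictions and their scalar summary for one candidate."""

    candidate: CatalystCandidate | None
    ddg: np.ndarray                # per-panel-reaction predicted ddG
    ddg_std: np.ndarray
    descriptor: np.ndarray         # per-panel-reaction predicted descriptor
    descriptor_std: np.ndarray
    activity: np.ndarray           # f per reaction
    median_ddg: float
    median_activity: float
    std_ddg: float
    std_activity: float
    valid: bool = True
    merit: float = math.nan        # filled per generation by the scalarizer

    def objective_row(self) -> np.ndarray:
        return np.array(
            [self.median_ddg, self.median_activity, self.std_ddg, self.std_activity]
        )

    @classmethod
    def invalid(cls, candidate=None) -> "FitnessVector":
        empty = np.array([])
        return cls(candidate, empty, empty, empty, empty, empty,
                   -np.inf, -np.inf, np.inf, np.inf, valid=False)


class PerformanceModel(Protocol):
    """Scores a catalyst SMILES against substrate pairs.

    Implemented by the surrogate pair (production) and by the synthetic
    landscape ground truth (benchmarks); both return per-pair arrays of
    (value, uncertainty).
    """

    def predict_selectivity(self, catalyst_smiles: str, panel: SubstratePanel
                            ) -> tuple[np.ndarray, np.ndarray]: ...

    def predict_descriptor(self, catalyst_smiles: str, panel: SubstratePanel
                           ) -> tuple[np.ndarray, np.ndarray]: ...


class SurrogatePerformanceModel:
    """Panel scoring through the two trained fingerprint ensembles.

    Selectivity calls use benzoic acid (or the configured co-catalyst) and
    the fixed solvent; descriptor calls use acetic acid, matching the
    contexts the models were trained for.  Tracks the number of underlying
    ensemble evaluations for memoization audits.
    """

    def __init__(self, selectivity_ensemble, descriptor_ensemble,
                 config: GAConfig = GAConfig()):
        from . import surrogate as _surrogate

        self._surrogate = _surrogate
        self.sel = selectivity_ensemble
        self.desc = descriptor_ensemble
        self.config = config
        self.call_count = 0

    def _records(self, catalyst: str, panel: SubstratePanel, cocatalyst):
        from .reactions import ReactionRecord

        return [
            ReactionRecord(sub_a=a, sub_b=b, catalyst=catalyst,
                           cocatalyst=cocatalyst, solvent=self.config.solvent)
            for a, b in panel.pairs
        ]

    def predict_selectivity(self, catalyst_smiles, panel):
        self.call_count += 1
        recs = self._records(catalyst_smiles, panel, self.config.cocatalyst_selectivity)
        return self._surrogate.predict_many(self.sel, recs)

    def predict_descriptor(self, catalyst_smiles, panel):
        self.call_count += 1
        recs = self._records(catalyst_smiles, panel, self.config.cocatalyst_descriptor)
        return self._surrogate.predict_many(self.desc, recs)


def evaluate_candidate(
    candidate: CatalystCandidate,
    panel: SubstratePanel,
    model: PerformanceModel,
    spec: ScalarizerSpec = ScalarizerSpec(),
) -> FitnessVector:
    """Panel predictions, Gaussian activity merits and their medians/spreads."""
    try:
        ddg, ddg_std = model.predict_selectivity(candidate.assembled_smiles, panel)
        desc, desc_std = model.predict_descriptor(candidate.assembled_smiles, panel)
    except (ValueError, AssemblyError):
        return FitnessVector.invalid(candidate)
    ddg = np.asarray(ddg, dtype=float)
    desc = np.asarray(desc, dtype=float)
    if not (np.all(np.isfinite(ddg)) and np.all(np.isfinite(desc))):
        return FitnessVector.invalid(candidate)
    f = np.array(
        [gaussian_activity(x, spec.activity_target, spec.activity_width) for x in desc]
    )
    return FitnessVector(
        candidate, ddg, np.asarray(ddg_std, float), desc, np.asarray(desc_std, float),
        f,
        float(np.median(ddg)), float(np.median(f)),
        float(np.std(ddg)), float(np.std(f)),
    )


def chimera_scalarize(matrix: np.ndarray, spec: ScalarizerSpec = ScalarizerSpec()) -> np.ndarray:
    """Totally ordered merit (larger = better) for a candidates x 4 matrix.

    Region-carving: objective 1 keeps candidates meeting the absolute ddG
    floor; each later objective keeps, within the surviving region, those
    within ``fraction`` of the population range of the region's best.
    Candidates are tiered by the number of leading objectives satisfied and
    ranked within a tier by the first unsatisfied (or, for full satisfiers,
    the last) objective.  Rows with non-finite entries fall to the worst
    tier.  Merit lies in [tier, tier + 1).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim == 1:
        M = M[None, :]
    n, k = M.shape
    objectives = spec.objectives
    if k != len(objectives):
        raise ValueError(f"expected {len(objectives)} objectives, got {k}")
    finite = np.all(np.isfinite(M), axis=1)

    # carve the feasible region objective by objective
    satisfied = np.zeros((n, k), dtype=bool)
    region = finite.copy()
    for j, (mode, value) in enumerate(objectives):
        col = M[:, j]
        if not region.any():
            break
        if mode == "threshold":
            sat = col >= value
        else:
            span = col[finite].max() - col[finite].min() if finite.any() else 0.0
            if mode == "maximize":
                sat = col >= col[region].max() - value * span
            else:
                sat = col <= col[region].min() + value * span
        satisfied[:, j] = sat & finite
        region = region & satisfied[:, j]

    # depth = number of leading satisfied objectives
    depth = np.zeros(n, dtype=int)
    for j in range(k):
        leading = satisfied[:, j] & (depth == j)
        depth[leading] = j + 1

    def oriented_score(j: int) -> np.ndarray:
        col = np.where(np.isfinite(M[:, j]), M[:, j], np.nan)
        mode = objectives[j][0]
        if not np.isfinite(col).any():
            return np.zeros(n)
        lo, hi = np.nanmin(col), np.nanmax(col)
        if not np.isfinite(lo) or hi == lo:
            s = np.full(n, 0.5)
        else:
            s = (col - lo) / (hi - lo)
            if mode == "minimize":
                s = 1.0 - s
        return np.where(np.isfinite(s), s, 0.0)

    merit = np.empty(n)
    for d in range(k + 1):
        tier = depth == d
        if not tier.any():
            continue
        rank_obj = min(d, k - 1)  # first unsatisfied, or last for full satisfiers
        merit[tier] = d + 0.999 * oriented_score(rank_obj)[tier]
    merit[~finite] = -1.0
    return merit


@dataclass
class GenerationRecord:
    generation: int
    population: list[FitnessVector]
    best_index: int
    best_changed: bool
    elite_merit: float  # merit of the carried-over previous best this generation

    @property
    def best(self) -> FitnessVector:
        return self.population[self.best_index]


class _Memo:
    """Fitness cache keyed by assembled canonical SMILES."""

    def __init__(self):
        self.cache: dict[str, FitnessVector] = {}
        self.hits = 0
        self.misses = 0

    def get_or_eval(self, candidate, fn: Callable[[], FitnessVector]) -> FitnessVector:
        key = candidate.assembled_smiles
        if key in self.cache:
            self.hits += 1
            return self.cache[key]
        self.misses += 1
        fv = fn()
        self.cache[key] = fv
        return fv


def _crossover(a: CatalystCandidate, b: CatalystCandidate,
               library: FragmentLibrary, rng: np.random.Generator
               ) -> tuple[str, dict[str, str]]:
    """Uniform per-slot-group crossover; cross-template pairs inherit one
    parent's template and re-draw slots the other parent cannot supply.
    Returns an unassembled (template_id, assignment) chromosome."""
    if a.template_id != b.template_id and rng.random() < 0.5:
        a, b = b, a
    template = library.template(a.template_id)
    a_assign = a.assignment_dict
    b_assign = b.assignment_dict if b.template_id == a.template_id else {}
    assignment: dict[str, str] = {}
    for slots, category in template.independent_groups():
        lead = slots[0]
        pick = a_assign.get(lead)
        if rng.random() < 0.5 and lead in b_assign:
            pick = b_assign[lead]
        if pick is None or library.fragment(pick).category != category:
            pool = library.category(category)
            pick = pool[rng.integers(len(pool))].id
        for s in slots:
            assignment[s] = pick
    return template.id, assignment


def _mutate(template_id: str, assignment: dict[str, str],
            library: FragmentLibrary, rate: float, rng: np.random.Generator
            ) -> tuple[str, dict[str, str]]:
    """Per-gene mutation: the template gene and each slot group mutate with
    probability ``rate``; fragments are replaced within their category."""
    template = library.template(template_id)
    if len(library.templates) > 1 and rng.random() < rate:
        template = library.templates[rng.integers(len(library.templates))]
    new_assignment: dict[str, str] = {}
    for slots, category in template.independent_groups():
        lead = slots[0]
        current = assignment.get(lead)
        if current is not None and library.fragment(current).category != category:
            current = None
        pool = library.category(category)
        if current is None or rng.random() < rate:
            current = pool[rng.integers(len(pool))].id
        for s in slots:
            new_assignment[s] = current
    return template.id, new_assignment


def evolve(
    config: GAConfig,
    library: FragmentLibrary,
    panel: SubstratePanel,
    model: PerformanceModel,
    spec: ScalarizerSpec = ScalarizerSpec(),
) -> list[GenerationRecord]:
    """Run the elitist GA and return the per-generation trajectory.

    Fully reproducible for a fixed config seed; candidate fitness is
    memoized by canonical SMILES, so re-visiting a chromosome performs no
    further model calls.
    """
    rng = np.random.default_rng(config.seed)
    memo = _Memo()
    assembled: dict[tuple, CatalystCandidate] = {}  # chromosome -> candidate

    def fitness(candidate: CatalystCandidate) -> FitnessVector:
        return memo.get_or_eval(
            candidate, lambda: evaluate_candidate(candidate, panel, model, spec)
        )

    population = [sample_random(library, rng) for _ in range(config.population_size)]
    trajectory: list[GenerationRecord] = []
    prev_best_key = None

    for gen in range(config.generations + 1):
        vectors = [fitness(c) for c in population]
        if not any(v.valid for v in vectors):
            raise RuntimeError(
                f"generation {gen}: every candidate failed evaluation; aborting"
            )
        merits = chimera_scalarize(np.stack([v.objective_row() for v in vectors]), spec)
        # snapshot the (memoized, shared) vectors so each generation record
        # carries the merit under its own population's thresholds
        snapshot = []
        for i, v in enumerate(vectors):
            if not v.valid:
                merits[i] = -1.0  # invalid rows are non-finite, but be explicit
            sv = copy.copy(v)
            sv.merit = float(merits[i])
            snapshot.append(sv)
        vectors = snapshot
        order = np.argsort(-merits, kind="stable")
        best_index = int(order[0])
        best_key = population[best_index].assembled_smiles
        elite_merit = float("nan")
        if prev_best_key is not None:
            for c, m in zip(population, merits):
                if c.assembled_smiles == prev_best_key:
                    elite_merit = float(m)
                    break
        trajectory.append(
            GenerationRecord(
                gen, vectors, best_index,
                best_changed=(best_key != prev_best_key),
                elite_merit=elite_merit,
            )
        )
        prev_best_key = best_key
        if gen == config.generations:
            break

        n_parents = max(2, math.ceil(config.selection_rate * config.population_size))
        parents = [population[i] for i in order[:n_parents]]
        next_pop: list[CatalystCandidate] = [
            population[i] for i in order[: config.elitism]
        ]
        attempts = 0
        while len(next_pop) < config.population_size:
            attempts += 1
            if attempts > 100 * config.population_size:
                raise RuntimeError("offspring generation stalled; aborting")
            pa = parents[rng.integers(len(parents))]
            pb = parents[rng.integers(len(parents))]
            try:
                tid, assign = _crossover(pa, pb, library, rng)
                tid, assign = _mutate(tid, assign, library, config.mutation_rate, rng)
                key = (tid, tuple(sorted(assign.items())))
                child = assembled.get(key)
                if child is None:
                    child = assemble(library.template(tid), assign, library)
                    assembled[key] = child
            except AssemblyError:
                continue
            # prefer unseen chromosomes: a duplicate of an already-scored
            # candidate spends a population slot on no new information, so
            # retry a few times before accepting it
            if child.assembled_smiles in memo.cache and attempts % 8 != 0:
                continue
            next_pop.append(child)
        population = next_pop

    evolve.last_cache_stats = {"hits": memo.hits, "misses": memo.misses}  # type: ignore[attr-defined]
    return trajectory


def trajectory_frame(trajectory):
    """Fig-8-style per-generation summary table."""
    import pandas as pd

    rows = []
    for rec in trajectory:
        b = rec.best
        rows.append(
            {
                "generation": rec.generation,
                "best_smiles": b.candidate.assembled_smiles if b.candidate else "",
                "best_template": b.candidate.template_id if b.candidate else "",
                "median_ddg": b.median_ddg,
                "median_f": b.median_activity,
                "std_ddg": b.std_ddg,
                "std_f": b.std_activity,
                "merit": b.merit,
                "best_changed": rec.best_changed,
            }
        )
    return pd.DataFrame(rows)


def pareto_front(points: np.ndarray, orientation: tuple[str, str] = ("max", "max")) -> list[int]:
    """Indices of non-dominated points in a 2-objective space.

    Sort-based sweep: orient both axes to "larger is better", sort by the
    first objective descending (second descending as tie-break), and keep
    points whose second objective exceeds the running maximum.  Weakly
    dominated points (equal on one axis, worse on the other) are excluded;
    duplicates of a front point are kept.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("expected an n x 2 array")
    Q = P.copy()
    for j, mode in enumerate(orientation):
        if mode == "min":
            Q[:, j] = -Q[:, j]
        elif mode != "max":
            raise ValueError(f"orientation must be 'min' or 'max', got {mode!r}")
    order = sorted(range(len(Q)), key=lambda i: (-Q[i, 0], -Q[i, 1]))
    front: list[int] = []
    for i in order:
        dominated = any(
            (Q[j, 0] >= Q[i, 0] and Q[j, 1] >= Q[i, 1])
            and (Q[j, 0] > Q[i, 0] or Q[j, 1] > Q[i, 1])
            for j in front
        )
        if not dominated:
            front.append(i)
    return sorted(front)
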