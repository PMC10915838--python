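"""Synthetic ground-truth landscapes for end-to-end benchmarking.

This module fabricates everything the pipeline consumes — fragment/template
libraries, substrate lists, reaction tables and energy profiles — with known
statistical structure, so that every stage can be tested against planted
truth without any external data:

* selectivity (ddG) and activity-descriptor ground truths are additive in
  template, fragment and substrate contributions plus optional sparse
  pairwise interactions, with Gaussian observation noise on emitted tables;
* energy profiles obey planted linear scaling relations in the descriptor,
  so the fitted volcano has an analytically known peak;
* the two targets are correlated through a trade-off parameter, emulating
  the selectivity/activity tension of real catalyst series.

All molecules are real, parseable small molecules (substituted indoles,
benzaldehydes, ureas, squaramides) so fingerprints are chemically
meaningful, but the planted effects attach to fragment and substrate
*identity*, not to their chemistry: the generator is a statistical stand-in
for curated literature data, not a physical model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .fragments import (
    CatalystCandidate,
    CatalystTemplate,
    Fragment,
    FragmentLibrary,
    canonical_smiles,
    enumerate_candidates,
    enumerate_count,
    sample_random,
)
from .reactions import ReactionRecord, SubstratePanel
from .volcano import EnergyProfile

# Monovalent substituents used for libraries and substrate decoration.
# Ring-closure digits 8/9 avoid clashes with host scaffolds (which use 1-3).
SUBSTITUENTS: tuple[str, ...] = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "C(F)(F)F",
    "O", "OC", "OCC", "OC(C)C", "N", "N(C)C", "C#N", "[N+](=O)[O-]", "C=C",
    "C#C", "CO", "CCO", "C(=O)OC", "C(=O)N", "C(=O)C", "S", "SC", "OC(F)(F)F",
    "c8ccccc8", "c8ccc(F)cc8", "c8ccc(Cl)cc8", "c8ccc(C)cc8", "c8ccc(OC)cc8",
    "c8ccc(C(F)(F)F)cc8", "c8cccc(C)c8", "Cc8ccccc8", "CCc8ccccc8",
    "C8CCCCC8", "C8CCCC8", "c8ccc9ccccc9c8", "C(c8ccccc8)c9ccccc9",
    "OCc8ccccc8", "N(C)c8ccccc8", "SC(F)(F)F", "CBr", "CCl", "CF", "C(C)O",
)

_SUBA_SCAFFOLDS = (
    "NCCc1c[nH]c2ccc({X})cc12",      # 5-substituted tryptamine
    "NCCc1c[nH]c2cc({X})ccc12",      # 6-substituted
    "NCCc1c[nH]c2c({X})cccc12",      # 7-substituted
    "NCCc1c({X})[nH]c2ccccc12",      # 2-substituted
    "N(Cc3ccccc3)CCc1c[nH]c2ccc({X})cc12",  # N(beta)-benzyl, 5-substituted
    "CNCCc1c[nH]c2ccc({X})cc12",     # N(beta)-methyl, 5-substituted
)

_SUBB_SCAFFOLDS = (
    "O=Cc3ccc({X})cc3",              # para-substituted benzaldehyde
    "O=Cc3cccc({X})c3",              # meta
    "O=Cc3ccccc3{X}",                # ortho
    "O=CC{X}",                       # aliphatic aldehyde
    "O=CC(C){X}",                    # branched aliphatic aldehyde
    "O=C(C(=O)OCC)c3ccc({X})cc3",    # aryl alpha-ketoester
    "O=C(C(=O)NC)c3ccc({X})cc3",     # aryl alpha-ketoamide
    "O=C(C(C)=O)c3ccc({X})cc3",      # aryl alpha-dione
    "O=C(C(=O)OC)C{X}",              # aliphatic alpha-ketoester
)

#: Planted scaling-relation lines, state -> (slope, intercept), kcal/mol.
#: Chosen so the C2 volcano peak (crossing of the TS2/reactants span with
#: the TS3/intermediate-2 span) sits at the descriptor value -9.0 kcal/mol.
PLANTED_LINES = {
    "C2": {
        "1": (0.30, 4.0),
        "TS2": (0.75, 12.8),
        "2": (1.0, 0.0),
        "TS3": (0.55, 2.0),
        "P": (0.0, -12.0),
    },
    "C3": {
        "1": (0.30, 4.0),
        "TS1": (0.78, 13.4),
        "1B": (0.60, 6.0),
        "TS2": (0.75, 12.8),
        "2": (1.0, 0.0),
        "TS3": (0.55, 2.0),
        "P": (0.0, -12.0),
    },
}
PLANTED_DGR = (0.0, -12.0)
PLANTED_PEAK = {"C2": -9.0, "C3": -9.268292682926829}  # analytic line crossings


def _spliced(scaffolds, substituents, n: int) -> list[str]:
    """First ``n`` distinct canonical molecules from scaffold x substituent."""
    seen: dict[str, None] = {}
    for scaffold, sub in itertools.product(scaffolds, substituents):
        smi = canonical_smiles(scaffold.replace("{X}", sub))
        seen.setdefault(smi, None)
        if len(seen) >= n:
            break
    if len(seen) < n:
        raise ValueError(f"only {len(seen)} distinct molecules available, need {n}")
    return list(seen)[:n]


def make_substrates(n_sub_a: int = 258, n_sub_b: int = 379) -> tuple[list[str], list[str]]:
    """Deterministic lists of distinct SubA (tryptamines) and SubB (carbonyls)."""
    return (
        _spliced(_SUBA_SCAFFOLDS, SUBSTITUENTS, n_sub_a),
        _spliced(_SUBB_SCAFFOLDS, SUBSTITUENTS, n_sub_b),
    )


def make_benchmark_library(
    n_r1: int = 6, n_r2: int = 5, n_r3: int = 10, n_r4: int = 15,
    include_cpa: bool = False,
) -> FragmentLibrary:
    """A small HBD library: a urea template (R1 x R2) and a squaramide
    template (R3 x R4); 180 candidates at the default sizes.  Optionally a
    BINOL-phosphate-like template with two symmetric R4 slots."""
    sizes = {"R1": n_r1, "R2": n_r2, "R3": n_r3, "R4": n_r4}
    offsets = {"R1": 0, "R2": 6, "R3": 11, "R4": 21}
    fragments = []
    for cat in ("R1", "R2", "R3", "R4"):
        for i in range(sizes[cat]):
            smi = SUBSTITUENTS[(offsets[cat] + i) % len(SUBSTITUENTS)]
            fragments.append(Fragment(f"{cat}_{i:02d}", smi, cat))
    templates = [
        CatalystTemplate(
            "urea", "urea", "O=C(N{R1a})N{R2a}",
            (("R1a", "R1"), ("R2a", "R2")),
        ),
        CatalystTemplate(
            "squaramide", "squaramide", "O=C1C(=O)C(N{R3a})=C1N{R4a}",
            (("R3a", "R3"), ("R4a", "R4")),
        ),
    ]
    if include_cpa:
        templates.append(
            CatalystTemplate(
                "cpa", "CPA-BINOL",
                "O=P1(O)Oc2ccc({R4a})cc2-c2cc({R4b})ccc2O1",
                (("R4a", "R4"), ("R4b", "R4")),
                symmetric_groups=(("R4a", "R4b"),),
            )
        )
    return FragmentLibrary(templates, fragments)


@dataclass
class LandscapeParams:
    """Magnitudes of the planted effects, in kcal/mol unless noted."""

    n_sub_a: int = 18
    n_sub_b: int = 18
    ddg_base: float = 1.2            # grand mean of the selectivity target
    template_sd: float = 0.5
    fragment_sd: float = 0.5
    substrate_sd: float = 0.4
    interaction_density: float = 0.05  # fraction of (fragment, substrate) pairs
    interaction_sd: float = 0.3
    noise_sigma_ddg: float = 0.3     # observation noise on emitted tables
    noise_sigma_descriptor: float = 0.5
    descriptor_center: float = 7.0   # weak-binding side of the volcano
    descriptor_template_sd: float = 2.0
    descriptor_fragment_sd: float = 1.5
    descriptor_substrate_sd: float = 1.0
    tradeoff: float = -0.4           # corr(fragment ddG effect, descriptor effect)
    state_noise: float = 0.5         # LFESR scatter in emitted profiles
    profile_x_mean: float = 7.0
    profile_x_sd: float = 6.0


@dataclass
class SyntheticLandscape:
    """Reproducible ground truth over a library and substrate lists."""

    seed: int
    params: LandscapeParams
    library: FragmentLibrary
    sub_a: list[str]
    sub_b: list[str]
    template_ddg: dict[str, float] = field(default_factory=dict)
    fragment_ddg: dict[str, float] = field(default_factory=dict)
    substrate_ddg: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    template_desc: dict[str, float] = field(default_factory=dict)
    fragment_desc: dict[str, float] = field(default_factory=dict)
    substrate_desc: dict[str, float] = field(default_factory=dict)
    lines: dict = field(default_factory=lambda: PLANTED_LINES)
    dgr_line: tuple[float, float] = PLANTED_DGR
    peak: dict = field(default_factory=lambda: PLANTED_PEAK)

    def _gene_fragments(self, candidate: CatalystCandidate) -> list[str]:
        template = self.library.template(candidate.template_id)
        assignment = candidate.assignment_dict
        return [assignment[slots[0]] for slots, _ in template.independent_groups()]

    def ddg_truth(self, candidate: CatalystCandidate, sub_a: str, sub_b: str) -> float:
        p = self.params
        v = p.ddg_base + self.template_ddg[candidate.template_id]
        frags = self._gene_fragments(candidate)
        v += sum(self.fragment_ddg[f] for f in frags)
        v += self.substrate_ddg[sub_a] + self.substrate_ddg[sub_b]
        for f in frags:
            v += self.interactions.get((f, sub_a), 0.0)
            v += self.interactions.get((f, sub_b), 0.0)
        return v

    def descriptor_truth(self, candidate: CatalystCandidate, sub_a: str, sub_b: str) -> float:
        p = self.params
        v = p.descriptor_center + self.template_desc[candidate.template_id]
        v += sum(self.fragment_desc[f] for f in self._gene_fragments(candidate))
        v += self.substrate_desc[sub_a] + self.substrate_desc[sub_b]
        return v


def make_landscape(
    seed: int,
    params: LandscapeParams | None = None,
    library: FragmentLibrary | None = None,
) -> SyntheticLandscape:
    """Deterministically plant all contributions from ``seed``."""
    params = params or LandscapeParams()
    if params.n_sub_a < 1 or params.n_sub_b < 1:
        raise ValueError("degenerate substrate list sizes")
    library = library or make_benchmark_library()
    sub_a, sub_b = make_substrates(params.n_sub_a, params.n_sub_b)
    rng = np.random.default_rng(seed)
    ls = SyntheticLandscape(seed, params, library, sub_a, sub_b)

    for t in library.templates:
        ls.template_ddg[t.id] = rng.normal(0.0, params.template_sd)
        ls.template_desc[t.id] = rng.normal(0.0, params.descriptor_template_sd)
    rho = params.tradeoff
    for f in library.fragments:
        d = rng.normal(0.0, params.fragment_sd)
        ls.fragment_ddg[f.id] = d
        indep = rng.normal(0.0, 1.0)
        z = d / params.fragment_sd if params.fragment_sd > 0 else 0.0
        ls.fragment_desc[f.id] = params.descriptor_fragment_sd * (
            rho * z + math.sqrt(1.0 - rho**2) * indep
        )
    for s in ls.sub_a + ls.sub_b:
        ls.substrate_ddg[s] = rng.normal(0.0, params.substrate_sd)
        ls.substrate_desc[s] = rng.normal(0.0, params.descriptor_substrate_sd)
    if params.interaction_density > 0:
        for f in library.fragments:
            for s in ls.sub_a + ls.sub_b:
                if rng.random() < params.interaction_density:
                    ls.interactions[(f.id, s)] = rng.normal(0.0, params.interaction_sd)
    return ls


def emit_reaction_table(
    landscape: SyntheticLandscape, n: int, seed: int
) -> list[ReactionRecord]:
    """Sample ``n`` noisy reactions from the landscape's ground truth.

    ddG observations are truth + N(0, sigma), clipped at zero (a racemic
    floor); descriptors get their own Gaussian noise.  Context is fixed to
    toluene/benzoic acid, as in the evolutionary experiments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = landscape.params
    records = []
    for _ in range(n):
        cand = sample_random(landscape.library, rng)
        a = landscape.sub_a[rng.integers(len(landscape.sub_a))]
        b = landscape.sub_b[rng.integers(len(landscape.sub_b))]
        ddg = max(
            landscape.ddg_truth(cand, a, b) + rng.normal(0.0, p.noise_sigma_ddg), 0.0
        )
        desc = landscape.descriptor_truth(cand, a, b) + rng.normal(
            0.0, p.noise_sigma_descriptor
        )
        records.append(
            ReactionRecord(
                sub_a=a, sub_b=b, catalyst=cand.assembled_smiles,
                cocatalyst="OC(=O)c1ccccc1", solvent="toluene",
                ddg=ddg, descriptor=desc, source="synthetic",
            ).completed()
        )
    return records


def emit_profiles(
    landscape: SyntheticLandscape, n: int, seed: int, mechanism: str = "C2"
) -> list[EnergyProfile]:
    """Energy profiles obeying the planted scaling relations.

    Descriptor values are drawn from the configured Gaussian; every other
    state's energy is its planted line plus N(0, state_noise), while state
    "2" is set exactly to the descriptor."""
    rng = np.random.default_rng(seed)
    p = landscape.params
    lines = landscape.lines[mechanism]
    out = []
    for i in range(n):
        x = rng.normal(p.profile_x_mean, p.profile_x_sd)
        states = []
        for label, (slope, intercept) in lines.items():
            if label == "2":
                e = x
            else:
                e = slope * x + intercept + rng.normal(0.0, p.state_noise)
            states.append((label, e))
        dgr = landscape.dgr_line[0] * x + landscape.dgr_line[1] + rng.normal(
            0.0, p.state_noise
        )
        out.append(EnergyProfile(f"{mechanism}_{i:04d}", mechanism, tuple(states), dgr))
    return out


def default_panel(landscape: SyntheticLandscape, k: int = 8, seed: int = 0) -> SubstratePanel:
    """A fixed random substrate panel for benchmark runs."""
    rng = np.random.default_rng(seed)
    pairs = set()
    while len(pairs) < k:
        pairs.add(
            (
                landscape.sub_a[rng.integers(len(landscape.sub_a))],
                landscape.sub_b[rng.integers(len(landscape.sub_b))],
            )
        )
    return SubstratePanel(tuple(sorted(pairs)), name="benchmark")


class TruthPerformanceModel:
    """Scores candidates with the landscape's exact ground truth.

    The independent oracle for GA benchmarks: same interface as the
    surrogate pair, zero uncertainty."""

    def __init__(self, landscape: SyntheticLandscape):
        self.landscape = landscape
        self.call_count = 0
        self._by_smiles = None

    def _candidate(self, smiles: str) -> CatalystCandidate:
        if self._by_smiles is None:
            self._by_smiles = {}
            for c in enumerate_candidates(self.landscape.library):
                self._by_smiles.setdefault(c.assembled_smiles, c)
        return self._by_smiles[smiles]

    def predict_selectivity(self, catalyst_smiles, panel):
        self.call_count += 1
        c = self._candidate(catalyst_smiles)
        vals = np.array(
            [self.landscape.ddg_truth(c, a, b) for a, b in panel.pairs]
        )
        return vals, np.zeros_like(vals)

    def predict_descriptor(self, catalyst_smiles, panel):
        self.call_count += 1
        c = self._candidate(catalyst_smiles)
        vals = np.array(
            [self.landscape.descriptor_truth(c, a, b) for a, b in panel.pairs]
        )
        return vals, np.zeros_like(vals)


def brute_force_optimum(
    landscape: SyntheticLandscape,
    panel: SubstratePanel,
    spec=None,
    max_space: int = 100_000,
) -> tuple[CatalystCandidate, np.ndarray]:
    """Exhaustive ground-truth optimum under the same scalarizer.

    Evaluates every candidate's true objective row over the panel, applies
    the Chimera scalarization to the full matrix, and returns the arg-max
    (lowest index on ties) together with the objective matrix.
    """
    from .evolve import ScalarizerSpec, chimera_scalarize
    from .volcano import gaussian_activity

    spec = spec or ScalarizerSpec()
    if enumerate_count(landscape.library) > max_space:
        raise ValueError(
            f"combinatorial space exceeds {max_space}; use a smaller library"
        )
    candidates = list(enumerate_candidates(landscape.library))
    rows = []
    for c in candidates:
        ddg = np.array([landscape.ddg_truth(c, a, b) for a, b in panel.pairs])
        desc = np.array(
            [landscape.descriptor_truth(c, a, b) for a, b in panel.pairs]
        )
        f = np.array(
            [gaussian_activity(x, spec.activity_target, spec.activity_width) for x in desc]
        )
        rows.append(
            [np.median(ddg), np.median(f), np.std(ddg), np.std(f)]
        )
    matrix = np.asarray(rows)
    merits = chimera_scalarize(matrix, spec)
    return candidates[int(np.argmax(merits))], matrix


def write_library(library: FragmentLibrary, fragments_path, templates_path) -> None:
    """Write the library in the ``fragments.csv``/``templates.csv`` format."""
    import pandas as pd

    pd.DataFrame(
        [{"id": f.id, "smiles": f.smiles, "category": f.category} for f in library.fragments]
    ).to_csv(fragments_path, index=False)
    pd.DataFrame(
        [
            {
                "id": t.id,
                "family": t.family,
                "scaffold": t.scaffold,
                "slots": ";".join(f"{n}:{c}" for n, c in t.slots),
                "symmetric_groups": ";".join("|".join(g) for g in t.symmetric_groups),
            }
            for t in library.templates
        ]
    ).to_csv(templates_path, index=False)
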