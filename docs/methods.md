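# Methods

This note documents the models, numerical choices and open design decisions
behind `gencat`, in the order the pipeline runs them.

## Selectivity encodings

Enantioselectivity is stored in three mutually consistent encodings: the
enantiomeric ratio er (major:minor, ≥ 1), the enantiomeric excess
ee = (er−1)/(er+1), and the activation free-energy difference between the
diastereomeric transition states, ΔΔG‡ = RT·ln(er) (kcal/mol, R =
0.0019872 kcal mol⁻¹ K⁻¹, default T = 298.15 K). ΔΔG‡ is kept as a
non-negative magnitude; the sign convention "which enantiomer is major" is
outside the package's scope. Readers complete missing encodings from
whichever is present and reject rows whose redundant encodings disagree
beyond 10⁻⁶ relative. ee is reported in percent by `ee_from_ddg`
(100·tanh(ΔΔG‡/2RT)); `ReactionRecord.ee` stores the fraction.

## Reaction representation and chemical-space maps

A reaction is featurized as concatenated Morgan fingerprints of its
components in the fixed order catalyst | co-catalyst | SubA | SubB |
solvent, 1024 bits per block (radius 2 by default; the radius is a
configuration field recorded with every model because circular-fingerprint
radii are a genuine free choice). An absent component contributes an
all-zero block, which keeps feature indices stable across reactions with
and without co-catalyst. Solvent names map to representative SMILES
through a small lookup table; unknown names are tried as SMILES and
otherwise zeroed.

Maps are exact full-SVD PCA to 100 components followed by t-SNE to 2D with
perplexity 30 (clamped below (n−1)/3 for small sets, as t-SNE requires).
Both stages are deterministic given the seed. Only determinism and
neighborhood preservation are contracted — t-SNE coordinates are not
comparable across implementations, so no test pins absolute positions.

## Farthest point sampling and the generality probing set

The substrate panel is selected on the 2D map by greedy maximin
("farthest point") sampling. Initialization is the point farthest from the
centroid, and all ties break to the lowest index, making panel selection
reproducible without a stored seed — a deliberate choice, since the panel
defines the optimization target and must be auditable. Distance is
Euclidean in the map, matching how the panel is visualized; fingerprint-
space (Jaccard) sampling would be a reasonable alternative but is not the
default.

## Energy profiles, scaling relations and TOF volcanoes

A catalytic cycle is an ordered list of relative Gibbs energies with the
separated reactants as the implicit zero reference and an overall reaction
free energy ΔG_r. Two mechanisms are carried: concerted C2 addition
(1 → TS2 → 2 → TS3 → P) and stepwise C3 addition through the
spiroindolenine (1 → TS1 → 1B → TS2 → 2 → TS3 → P).

Turnover frequency uses the energy-span model. The span δE is the maximum
over (transition state Tᵢ, intermediate Iⱼ) pairs of Tᵢ − Iⱼ when the TS
follows the intermediate in the cycle and Tᵢ − Iⱼ + ΔG_r when it precedes
it; TOF = (k_BT/h)·exp(−δE/RT) with k_B/h = 2.0837×10¹⁰ s⁻¹K⁻¹
(log₁₀(k_BT/h) = 12.793 at 298.15 K). The max-span form is the default
because it is closed-form testable; the smoothed summed form
(k_BT/h)(e^{−ΔG_r/RT} − 1)/Σᵢⱼ e^{(span_ij − ΔG_r)/RT} is used only inside
the degree-of-TOF-control weights, where its analytic partition-of-unity
property is wanted. Those weights are computed by central differences
(step 10⁻⁴ kcal/mol) of ln TOF with respect to each TS energy, clipped at
zero; they sum to 1 within 10⁻⁶.

LFESRs are per-state ordinary least squares of state energy against the
descriptor ΔG_RRS(2) — the relative energy of the protonated
tetrahydro-β-carboline intermediate 2. The descriptor's own relation is
the identity by definition; ΔG_r is fitted like a state; states observed
fewer than 3 times are flagged unfittable. The volcano curve evaluates the
max-span TOF on profiles reconstructed from the fitted lines over a
descriptor grid (default −25…+25 kcal/mol, 201 points; |x| > 100 is
rejected as unphysical). The 95% band is a conservative envelope: each
state is shifted by ±t₀.₉₇₅,ₙ₋₂·(residual SE), transition states down and
intermediates up for the upper edge (ΔG_r down, since raising it enlarges
the TS-precedes-intermediate spans), and vice versa. The peak is the grid
argmax refined by bounded scalar minimization between its neighbors
(xatol 10⁻⁶).

Activity merit is the unit-peak Gaussian f = exp(−(x−x*)²/2σ²) around the
volcano-peak target x* = −9.0 kcal/mol. The width σ defaults to
3.0 kcal/mol — about the scale over which the volcano top flattens — and
is configurable; "normalized" is interpreted as unit peak height so
f ∈ (0, 1].

## Surrogate ensembles

Both surrogates (selectivity ΔΔG‡; activity descriptor) are ensembles of
XGBoost regressors trained on 100 independent random 90/10 splits (default
hyperparameters; a random-forest mode via `XGBRFRegressor` is exposed
because tree-ensemble flavor is a genuine free choice here, and the choice
is recorded in model metadata). A prediction is the member mean; its
uncertainty is the member (population) standard deviation. Out-of-fold
error averages, per row, the predictions of the members that held that row
out — with 100 splits each row is held out ~10 times.

For the descriptor model, reactions catalyzed by cinchona alkaloids
(detected by a quinuclidine substructure match) are excluded because those
bifunctional catalysts follow a different mechanism, and the co-catalyst
is coerced to a three-level encoding — any carboxylic acid → acetic acid,
any acyl/benzoyl halide → benzoyl bromide, else none — mirroring how the
underlying profiles treat the acid co-catalyst. The selectivity model uses
the real co-catalyst identity and includes the solvent block.

Persistence writes each member as an XGBoost Booster JSON dump plus a
metadata file (target, fingerprint config, seed, split indices); reloading
reproduces predictions bit-for-bit on the same platform.

## Hierarchical scalarization

Four objectives over the substrate panel, in fixed priority order:
median ΔΔG‡ (absolute floor 2.0 kcal/mol), median f (maximize, 10%
degradation tolerance), std of ΔΔG‡ and std of f (minimize, 25% compromise
each). The scalarizer carves the population region objective by objective:
the floor is absolute; for maximize/minimize objectives the threshold is
the surviving region's best ± fraction × the population range of that
objective. Candidates are tiered by the number of leading thresholds
satisfied and ranked within a tier by the first unsatisfied (or, for full
satisfiers, the last) objective; the merit is tier + 0.999 × a
range-normalized score of that ranking objective, giving a total order in
which larger is better. Non-finite rows fall to a sub-zero tier. In the
zero-tolerance limit this reduces to lexicographic ordering, which is the
property the tests pin; the exact merit arithmetic of achievement
scalarizers varies between implementations, so ordering behavior rather
than a literal formula is the contract.

Because thresholds are population-relative, merit *values* are not
comparable across generations. The monotonicity guarantee is therefore
stated within generations: with elitism the generation best always ranks
at least as high as the carried-over previous best under the same
thresholds (`GenerationRecord.elite_merit` stores the comparison).

## Genetic algorithm

Defaults: population 10, 50 generations, mutation rate 0.10 per gene,
truncation selection of the top 25% as the parent pool, elitism 1.
A chromosome is a template gene plus one fragment gene per independent
slot group (symmetric groups, e.g. the 6/6′ positions of a BINOL/SPINOL
phosphoric acid, are one gene). Crossover is uniform per slot group
between two parents; when parents carry different templates the child
inherits one parent's template and re-draws slots the other parent cannot
supply, so offspring are always assemblable. Mutation replaces a fragment
uniformly within its category (the template gene mutates likewise).
Candidate fitness is memoized by canonical SMILES: re-evaluating a seen
candidate performs zero surrogate calls (audited via call counts).
Offspring generation prefers unseen chromosomes — a duplicate of an
already-scored candidate is retried a few times before being accepted —
because with a 10-individual population duplicates otherwise dominate late
generations and exploration stalls at a small fraction of the space;
duplicates remain legal and share memoized fitness. Evaluation failures
(unparseable assembly, featurization errors) demote the candidate to the
worst tier instead of crashing the run. Everything is driven by one seeded
generator, so runs are exactly reproducible.

Pareto fronts over (median ΔΔG‡, median f) are extracted post hoc from
trajectories with a dominance filter that excludes weakly dominated
points; orientation is explicit per axis.

## Synthetic benchmark

The generator stands in for curated literature data and DFT profiles; it
is a statistical emulator, not a physical model, and that is its point:
planted truth makes every stage falsifiable offline.

* **Molecules.** All SMILES are real small molecules — substituted
  tryptamines (six decoration patterns, including Nβ-benzyl and Nβ-methyl
  protection) for SubA, substituted benzaldehydes, aliphatic aldehydes,
  α-ketoesters/amides/diones for SubB, urea and squaramide scaffolds for
  catalysts — so fingerprints carry meaningful structure. Planted effects
  attach to fragment/substrate *identity*, not chemistry.
* **Selectivity truth** is additive: base 1.2 kcal/mol + template
  (σ 0.5) + fragment (σ 0.5 each) + substrate (σ 0.4 each) terms, plus
  sparse fragment×substrate interactions (density 0.05, σ 0.3 kcal/mol).
  These scales put typical ΔΔG‡ in the 0–3 kcal/mol range seen across
  organocatalyst classes, with the 2 kcal/mol generality floor attainable
  by a minority of candidates. Observations add N(0, σ) noise (default
  σ = 0.3 kcal/mol; individual studies may pass 0.2) and clip at zero, a
  racemic floor.
* **Descriptor truth** is analogous, centered at +7 kcal/mol (the
  weak-binding slope of the volcano, where most real reactions sit) with
  larger scales (template σ 2.0, fragment σ 1.5, substrate σ 1.0), and its
  fragment effects are correlated with the selectivity effects through a
  trade-off parameter ρ = −0.4, reproducing the selectivity/activity
  tension that makes the multi-objective problem non-trivial.
* **Profiles** obey planted lines per state; slopes/intercepts are chosen
  so the ascending (TS2 vs reactants) and descending (TS3 vs intermediate
  2) spans cross at exactly −9.0 kcal/mol for C2 (−9.27 for C3, keeping
  the two volcanoes close). State energies add N(0, 0.5) scatter;
  descriptors are drawn N(7, 6), emulating the observed distribution.
* **Benchmark sizes.** The default library spans 180 candidates
  (urea 6×5 + squaramide 10×15), a space small enough for exhaustive
  ground-truth evaluation yet large enough that a 500-evaluation GA run
  cannot enumerate it; panels default to 8 pairs, reaction tables to 500
  rows. Tests and the acceptance script use reduced fingerprint widths
  and tree counts where the check is about behavior rather than accuracy.

What passing benchmarks do **not** show: that fingerprints extrapolate
across real catalyst chemotypes, that literature noise is Gaussian or
independent of the catalyst, or that real Pictet–Spengler energetics are
linear in the descriptor. The planted structure matches the pipeline's
assumptions by construction; real-data performance is an empirical
question the synthetic suite cannot answer.

## Known limitations

* Fragment attachment is single-point; polyvalent linkers are out of scope.
* Combinatorial counts are over assignments; distinct assignments that
  canonicalize to the same molecule are counted separately (deduplicated
  SMILES counts are available by enumeration on small libraries).
* The volcano band propagates per-state regression error as a worst-case
  envelope, which overstates joint uncertainty when state errors are
  correlated.
* The GA assumes surrogate calls are cheap; no asynchronous or distributed
  evaluation is provided.
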