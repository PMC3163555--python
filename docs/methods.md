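# Methods

This note records the models behind `retrosig`, the conventions adopted
where a design choice was genuinely open, and what the synthetic study
conditions do and do not demonstrate.

## Molecular graphs and canonical signatures

Molecules are hydrogen-suppressed heavy-atom graphs; each atom carries
element, formal charge and attached-hydrogen count, folded into its label
(`[CH3]`, `[N+H3]`, `[O-]`). Bonds are single/double/triple/aromatic;
aromatic rings are perceived (never kekulised) so that, e.g., all benzene
carbons are equivalent. Stereochemistry is ignored: the signature is a 2D
descriptor.

The atomic signature of height h is a canonical string for the subgraph
induced by all atoms within h bonds of the root. Canonical form is
*defined* as the lexicographic minimum, over all orderings of the
subgraph's atoms (root first), of a predecessor-adjacency serialisation:
each placed atom contributes a chunk (back-edge count, label, sorted
back-edges with bond symbols), and chunks favouring connectivity sort
first so the minimum is attained on connected orders. The minimum is
computed exactly by branch-and-bound with tie branching; a brute-force
permutation minimiser ships alongside as an independent oracle and the
two are asserted equal on all small fixtures. This makes permutation
invariance and rooted-isomorphism invariance true by construction rather
than by grammar convention.

Molecular signatures are multisets of atomic signatures (counts sum to
|V|); reaction signatures are the stoichiometry-weighted product-minus-
substrate difference, with exact cancellation of unchanged substructure.

## Reaction similarity and its calibration

Two representations of a reaction coexist, for different jobs:

* **Equality searches** (extended-space generation) use the
  hydrogen-suppressed single-height representation above. Under it the
  two amidohydrolase reactions of the worked example share their
  signature at h = 1 and first differ at h = 2.
* **Similarity scoring** (Tanimoto, clustering, promiscuity, tensor
  kernels) uses a calibrated hydrogen-inclusive representation:
  hydrogens become explicit degree-1 vertices, the signature dictionary
  is cumulative over all radii up to the horizon, and the horizon for
  heavy height h is h + 1 — the extra layer carries the hydrogen
  envelope of the outermost heavy shell. The Tanimoto coefficient splits
  the signed vector into substrate and product parts and takes
  Σmin/Σmax.

The second convention was fixed by calibration against the worked
example: it is the representation under which the amidohydrolase pair
scores exactly 1.0 while their signatures agree and 0.81 at h = 2, the
value the similarity system is anchored to. Hydrogen-suppressed
similarity and a dot-product Tanimoto ⟨a,b⟩/(⟨a,a⟩+⟨b,b⟩−⟨a,b⟩) (clamped
at 0 for anticorrelated vectors) remain available through `RunConfig`
(`similarity_representation`, `tanimoto_convention`).

## Extended metabolic reaction space

Compounds are partitioned into signature classes at height h; every
participant of every nominal reaction is substituted (cross-product over
roles) by its class members, inheriting stoichiometric coefficients.
Height 0 — elemental-formula Diophantine enumeration — is explicitly
unsupported: its solution sets are unusably large. Duplicates (by
substrate multiset, product multiset, direction) of nominal or earlier
putative reactions are suppressed, as are identity substitutions and
degenerate null transformations. Caps (default 1000 substitutions per
reaction, 50 compounds per class) truncate deterministically with a
logged warning. Every putative reaction provably preserves its parent's
reaction signature at the generation height, including the h = 0
elemental balance.

Thermodynamic screening: a compound's ΔG is the sum of contributions of
its structural subgroups, keyed by atomic signatures at a configured
height (default 1); ΔG_r is the product-minus-substrate balance. Putative
reactions with ΔG_r above threshold (default 0 kJ/mol) plus tolerance
(default 5 kJ/mol) are removed; reversible ones survive if either
direction passes, with the feasible direction flagged; reactions touching
subgroups absent from the table are kept and flagged `unscored` — the
filter must not silently discard for lack of coverage. Nominal reactions
are never removed. No pH or ionic-strength corrections are applied.

## Retrosynthetic enumeration

The network maps to a directed hypergraph; reversible reactions
contribute two directed hyperedges. A pathway for target c is a *set* of
directed hyperedges such that c is produced, every substrate of every
edge is a chassis metabolite, a currency metabolite, or produced by
another edge, an acyclic firing order exists, and no single edge is
removable (minimality). Enumeration is an AND/OR backward search: the
lexicographically smallest open compound is satisfied either by an
already-chosen producer (covering byproducts) or by branching over new
producing edges; self-consuming edges are rejected for the compound they
are meant to produce; candidate sets are validated and deduplicated by
reaction-set identity. Results are ordered by length, then edge ids.

Currency metabolites (water, ATP/ADP, NAD(P)(H), CoA, phosphate, O2,
CO2, ammonia by id; configurable) count as satisfied substrates and are
never expanded — without this the recursion explodes on cofactor
regeneration. An endogenous target returns the empty (native) pathway
first plus any non-empty alternatives, so native-route validation can
rank native production. Defaults: depth 10 reactions, 10⁴ pathways,
deterministic truncation with warning. Optimal-hyperpath search being
NP-hard in general, full bounded enumeration followed by ranking is the
deliberate strategy; no additive-cost shortest-hyperpath reduction is
implemented.

## Predictors

* **String kernel**: cosine-normalised k-mer spectrum kernel (default
  k = 3) over amino-acid sequences; Gram matrices are positive
  semidefinite with unit diagonal.
* **Promiscuity**: promis(S) = 1 − min pairwise calibrated similarity of
  the enzyme's catalysed reactions (mean aggregation available);
  single-reaction enzymes score 0. The sequence-based estimator is a
  Platt-calibrated SVM on the precomputed spectrum Gram matrix; any
  learner accepting a Gram matrix satisfies the contract.
* **Reaction clustering**: average-linkage agglomerative clustering on
  d = 1 − similarity; the cluster count maximises the average silhouette
  over the scanned range, ties toward fewer clusters, and degenerate
  inputs (all-identical reactions) collapse to one cluster by
  convention.
* **Candidate enzymes**: a putative reaction is assigned to its nearest
  cluster by average similarity; candidates are enzymes with known
  reactions there, scored by an SVM over the tensor-product kernel
  (sequence kernel × reaction similarity) trained on known pairs against
  seeded random negative pairs, or — when fewer than 8 positive pairs
  exist — by the maximum tensor kernel to any known pair. Ties break by
  enzyme id.
* **Performance**: per-cluster regression trees predicting
  log₁₀(k_cat/K_M) from reaction descriptors (participant counts,
  signature-difference size and mass) and sequence descriptors (length,
  hydrophobic and charged fractions). Leaves hold at least two records
  so predictions average out measurement noise rather than memorising
  single observations. Outputs are min-max normalised to [0, 1] over the
  cluster's training range and clipped; clusters with fewer than five
  records fall back to the documented constant 0.5 with a warning.
* **Compatibility**: descriptors are sequence length, GC content (unset
  without a nucleotide sequence), phylogenetic distance (shortest path
  in a user-supplied parent-child taxonomy tree; 0 for the same
  organism), hydrophobic and charged residue fractions, Chou-Fasman
  helix/sheet/turn propensity means as a lightweight secondary-structure
  distribution, and an inclusion-body propensity surrogate — a logistic
  function of mean Kyte-Doolittle hydropathy and length. Missing
  descriptors are mean-imputed from training. The scorer is a
  standardised SVM trained on the chassis' own sequences against a
  balanced, seeded sample of other organisms' sequences; het(S) is the
  positive-class probability. Gene-rank p-values follow the uniform
  null: p = rank/total.
* **Toxicity**: PLS regression of log₁₀ IC₅₀ on deterministic 2D
  descriptors — molecular weight, heteroatom fraction (solubility
  surrogate), mean standard bond length by bond order, a carbon-balance
  partition-coefficient surrogate, an additive van-der-Waals surface
  surrogate, and signature-richness. Components are reduced with a
  warning if the descriptor matrix is rank-deficient; leave-one-out Q²
  is reported; tox(p) = 1/predicted IC₅₀ on the linear scale.

## Ranking and weight optimisation

cost(r\*, S) = ω_p(1 − promis) + ω_e(1 − perf) + (1 − het) is bounded in
[0, ω_p + ω_e + 1] and strictly decreasing in each score; reactions with
no candidate enzyme are charged the worst-case penalty so they are
dominated, not excluded. W(c, ρ) adds λ_path-weighted summed enzyme
costs, λ_tox-weighted toxicity summed over each reaction's products
(a compound produced by two reactions counts once per producing
reaction), and λ_flux·1/(1 + v_c) — the simplest bounded decreasing
transform of the nominal flux; −log alternatives would serve equally and
the additive combination is this package's convention. Ranking is
ascending in W with (length, id) tie-breaks and is invariant under
uniform positive scaling of the three λ, which is why λ_path is pinned
to 1 during optimisation. Ranking accuracy y_ρ = (n_TP + n_TN)/|ρ(c)|
counts annotated pathways at the same or better score and predicted
pathways strictly below; the optimiser grid-searches (λ_tox, λ_flux)
(default grid 0..2 step 0.01; coarser grids configurable) maximising the
aggregate Σy_ρ, ties toward the smallest weights, with modes that zero
out either parameter when only one data source is available.

## Flux balance

Stoichiometric models carry S, per-reaction bounds (defaults ±1000
mmol·gDW⁻¹·h⁻¹), a biomass objective and exchange ids; JSON round-trip
and SBML Level 3 core import (fbc bounds honoured) are provided.
Augmenting a model adds one irreversible column per pathway hyperedge
(reverse edges flip signs) and an irreversible sink for the target.
The bilinear objective f = v_c·Z is not an LP, so it is solved by a
deterministic growth-fraction sweep: compute Z_max, then for each φ on a
21-point grid over (0, 1] maximise v_c subject to Z ≥ φ·Z_max, returning
the grid point with maximal v_c·Z. The scheme is exact whenever
production does not compete with growth (φ = 1 is always on the grid)
and within grid resolution otherwise; refining the grid never decreases
the returned objective. Degenerate alternate optima are possible: only
objective values and constraint satisfaction are contractual, never
individual fluxes. Models with no feasible growth report v_c = 0 with a
`no-growth` flag. Knockout-style questions are answered by re-solving
with modified bounds; no bespoke algorithm is claimed.

## Synthetic study conditions

The fixtures module defines the conditions every recovery experiment
runs under; the same spec is always byte-identical.

* **Toy network**: 4 chassis metabolites, water as currency, two nominal
  routes to the target (a branch point), and per planted pair an ether
  isomer duo C_p–O–C_q / C_{p+1}–O–C_{q−1} (p + q fixed, both tails
  ≥ 3 carbons) — structurally distinct molecules with identical
  height-1 molecular signatures that separate by height 3. With no
  planted pairs the expansion adds nothing at any height.
* **Sequences**: 200 promiscuity-training sequences (80–150 residues),
  half carrying three copies of a 5-residue motif; 24 enzymes (150–400
  residues) over 5 organisms in a 2-clade taxonomy.
* **Kinetics**: log₁₀(k_cat/K_M) = 2.0 plus a 2.0 jump for sequences
  longer than 270 residues, with σ = 0.15 noise.
* **Toxicity**: 24 small molecules; log₁₀ IC₅₀ linear in three package
  descriptors, noiseless by default.
* **Compatibility**: chassis genes at GC 0.625 versus background 0.375.
* **Ranking corpora**: 6 compounds × 5 pathways, one annotated each,
  annotated routes carrying 1.5 lower summed toxicity.

These fixtures emulate the statistical structure the method relies on —
signature degeneracy, branch points, planted predictive signal — but not
real data's size, class imbalance, label noise, phylogenetic covariance
or chemistry breadth. Passing recovery tests therefore demonstrates
correctness of the machinery at the stated effect sizes, not performance
on genome-scale databases; published genome-scale counts are outside
what a self-contained package can or should reproduce.

## Problem sizes and numerical choices

The test suite and the acceptance script run toy networks of ≤ 14
compounds, random hypergraphs of ≤ 10 reactions against exhaustive
subset oracles (50 graphs), 50-seed weight-recovery sweeps on a
5-point λ grid, and LP models of ≤ 4 reactions — sizes chosen so every
oracle can be exact. Tolerances: mass balance to 1e-9, W decomposition
to 1e-12, Gram positive semidefiniteness to 1e-8, silhouette tie-break
at 1e-12. All stochastic components consume a single seeded generator;
nothing reads global random state.

## Known limitations

Canonicalisation is exponential in the worst case (branch-and-bound over
orderings); it is exact and fast on small-molecule neighbourhoods but
not suitable for very large symmetric graphs. Substitution inherits the
parent's stoichiometric coefficients — coefficients are not re-searched.
The inclusion-body and solubility descriptors are deterministic
surrogates, not validated predictors. Pathway enumeration is exhaustive
within bounds, hence exponential on dense networks; the height h is the
intended complexity control.
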