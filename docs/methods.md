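# Methods

## Metabolic models and flux balance analysis

A model is a stoichiometric matrix S (m metabolites × n reactions) with
reversibility flags, flux bounds, a gene–protein–reaction (GPR) map, a
currency-metabolite list, and an objective reaction. Sign conventions are
standard: s_ij ≤ −1 marks metabolite i as a reactant of reaction j, s_ij ≥ 1
as a product; rev_j ∈ {0, 1} flags irreversibility/reversibility, enforced as
lb_j ≥ 0 for irreversible reactions. GPR rules are OR-of-ANDs: a list of
isozymes, each a set of complex subunits. Infinite bounds are capped at 1000
flux units so every linear program is bounded.

FBA solves max/min c·v s.t. S·v = 0, lb ≤ v ≤ ub with HiGHS
(`scipy.optimize.linprog`). Only the optimum value is consumed downstream,
so degeneracy of the optimal flux vector is irrelevant. Optimal solutions
satisfy ‖S·v‖∞ ≤ 1e−9·(1 + max|v|), which the tests assert.

A *metabolic task* asks whether required outputs are producible from allowed
inputs: all boundary exchanges are closed, allowed inputs are opened up to
their caps, and each required output receives a temporary sink with a lower
bound at the minimum production; the task passes iff the LP is feasible.
*Viability* = objective optimum > ε (default ε = 1e−6, configurable; the
threshold exists because "non-zero growth" is not a meaningful floating-point
predicate) AND all tasks feasible.

Reaction deletion closes bounds to [0, 0] instead of removing columns, so
matrix indices, derived networks and GPR maps stay aligned across modules.
The test suite contains an independent oracle that *does* rebuild models
structurally per deletion and re-solves from scratch; both screens are
asserted equal to it on the toy and 20+ random models.

## Context-specific model extraction

Expression values (FPKM-like) are binned per gene and sample:
none (< 1), low (1 ≤ · < 10), medium (10 ≤ · < 50), high (≥ 50); boundaries
are half-open with the boundary value entering the upper bin. Reaction
evidence aggregates gene bins through the GPR (min over complex members, max
over isozymes); reactions without a rule receive a neutral sentinel and are
always kept, as are boundary exchanges — there is no expression evidence
against them.

The extractor keeps every reaction with evidence bin ≥ 1, then greedily
re-adds excluded reactions (ties broken lexicographically) until the context
passes its group's objective and tasks, flagging contexts that cannot be
repaired. This is a deliberately simple, deterministic stand-in for
MILP-based task-driven extraction methods: it preserves the properties that
matter downstream (determinism, functionality by construction, monotonicity
in evidence) at a fraction of the machinery. Cancer contexts use the biomass
reaction as objective — growth is part of their functionality definition —
and non-cancer contexts use the ATP-consumption reaction.

## Screens and toxicity

Antimetabolite screen: for each base metabolite name, regardless of
compartment, remove every kept reaction in which any instance is consumed —
the reactant side for irreversible reactions, either side for reversible
ones (a reversible reaction has no fixed substrate side). Currency
metabolites are screened like any other; they are excluded only from derived
networks. Gene silencing removes reactions whose GPR fails with the gene
absent (an isozyme survives if any complex excluding the gene is complete).

A perturbation is lethal in a context iff the context loses viability
(objective + that group's tasks — the uniform viability definition is used
for both screens and both groups). The toxicity filter keeps targets lethal
in ≥ `cancer_fraction` of cancer contexts (default 1.0 — all of them) with
an empty non-cancer toxicity set, and annotates the all-contexts /
any-context tiers for reporting.

## Derived networks

MMN: nodes are non-currency metabolites of active reactions; each reaction
contributes substrate→product edges for every (substrate, product) pair,
both orientations for reversible reactions. Co-substrates are *not* linked:
edge semantics are producer→consumer throughout, matching the RRN
definition. RRN: edge r1→r2 iff a non-currency product of r1 is a substrate
of r2. Self-loops are dropped (simple graphs). The adjacency convention is
A[target, source] = 1, i.e. rows collect incoming influence as in
x' = Ax + Bu; node order is the sorted node ids and is recorded in every
export (GraphML, SIF, Matrix Market + node-order sidecar).

A default currency list ships with the package (ATP, ADP, AMP, NAD(H),
NADP(H), FAD(H2), H2O, H+, Pi, PPi, CO2, O2, CoA), overridable per model.

## Exact controllability

N_D = max_λ μ(λ) with μ(λ) = N − rank(λI − A); the maximizing eigenvalue is
λ_M (ties broken deterministically: λ = 0 preferred, then smallest modulus,
then smallest argument). Ranks use singular values with tolerance
N·σ_max·1e−10; complex eigenvalues are handled over the complex field.

**Numerical choice that matters.** Numerically computed eigenvalues of a
defective (Jordan-block) eigenvalue scatter at radius ~eps^(1/k) for block
size k — about 1e−8 at k = 2 and 2e−3 at k = 6 — so no fixed clustering
tolerance can reliably reunite them. Multiplicities are therefore probed at
chain-clustered eigenvalue representatives *plus* their nearest
Gaussian-integer snaps, and always at 0: degenerate eigenvalues of
unweighted adjacency matrices concentrate on integers (0 from path/star
structure, −1 from cliques). Probing a non-eigenvalue is harmless — the
matrix has full rank there and contributes μ = 0. A test-only exact oracle
(see below) confirms 100% agreement on hundreds of seeded random digraphs.

The canonical MDS consists of the nodes whose rows of (λ_M I − A), processed
in node order, are linearly dependent on earlier rows; its size must equal
N_D or an internal-consistency error is raised. The driver configuration is
certified with PBH at every eigenvalue. One subtlety: a single-attachment
input at each λ_M driver does not always cover *other* degenerate
eigenvalues (e.g. an isolated node plus a strongly connected component —
every single column fails at some eigenvalue even though N_D = 1). As in
the exact-controllability framework, an input signal may attach to several
nodes: the certified input matrix keeps N_D columns anchored at the driver
set and attaches supplementary nodes (the other eigenvalues' dependent rows)
round-robin, falling back to deterministic non-uniform weights if unit
attachments cancel. `verify_pbh(strict=True)` remains available for the
plain indicator-column check.

Dispensability: remove each node (row + column) and recompute N_D on the
N−1 network; increase → indispensable, decrease → dispensable, unchanged →
neutral. A removal leaving one node uses the convention N_D = 1.
Controlling nodes = MDS ∪ indispensable. Cancer-specific controlling nodes
appear in ≥ `min_cancer` cancer networks (default 1) and in zero non-cancer
networks, and carry the count of cancer networks ("number of patients")
plus a merged origin tag.

By default metabolite-level controlling nodes come from the MMN (pooled to
compartment-free base names; a base name is controlling if any instance is)
and gene-level ones from the RRN (a gene is controlling iff ≥ 1 reaction it
catalyzes is, inheriting the maximum patient count).

### Exact-arithmetic oracle

`exact_oracle.exact_nd` recomputes N_D without floating point: factor the
characteristic polynomial over Q; for each irreducible factor f, every root
has geometric multiplicity (n − rank f(A))/deg f — ker f(A) is the direct
sum of the eigenspaces of f's roots, which carry isomorphic Jordan
structures — and both f(A) (Horner, integer matrices) and its rank are exact
rational computations. The oracle never materializes an eigenvalue and is a
verification tool only, never the production path.

## Prioritization

Candidates = screen survivors ∩ cancer-specific controlling nodes. Degree
(in+out) and betweenness (directed shortest-path, normalized by
(N−1)(N−2) so networks of different sizes are comparable) are aggregated —
mean by default, median configurable — over the cancer networks containing
the node; gene centralities take the maximum over catalyzed reactions,
metabolite centralities the maximum over compartment instances. The
indispensable block (including "both"-origin targets) is ranked by degree
and precedes the MDS block ranked by betweenness; ties break by patient
count, then id. Block order is a configuration, with indispensable-first as
the default because degree-ranked indispensable nodes are the primary
read-out of the method.

## Synthetic data: what it emulates and what it does not

The planted cohort emulates a two-group expression study over a small GEM
(default 5 cancer + 5 non-cancer samples; the analysis scales linearly in
samples). Its reference model routes carbon to biomass through an
intermediate X (R2A: A+ATP→X+ADP by g2a; R2B: X→B by g2b) with a bypass
R5: A→B (g5); a transporter regenerates ATP so the ATP-consumption objective
is carbon-coupled. Cancer samples silence g5 (log-normal FPKM, median 0.05);
all other genes have median 100 with σ = 0.3 — two bins away from every
relevant threshold, so binning noise cannot change any context's content and
pass/fail outcomes are seed-independent. By construction the anticancer
non-toxic controlling targets are exactly {g2a, g2b, X}, with R2B the
highest-degree controlling reaction, so g2b must rank first; all other genes
are either toxic (g1, g3, g4), non-lethal (g5), or — for every other
metabolite — toxic in non-cancer contexts.

What passing on this cohort shows: every filter (lethality, toxicity,
cancer-specific controllability, centrality ranking) behaves exactly as
specified on a system whose ground truth is enumerable by hand. What it
does not show: behavior on genome-scale networks (thousands of reactions,
dense currency coupling, alternative optima), realistic expression noise and
batch structure, or biological validity of any particular target class.
Random toy models (seeded linear backbones with bypasses, isozymes and
complexes, 10–30 reactions) broaden structural coverage for the
screen-vs-oracle equivalence checks.

## Problem sizes and determinism

Default verification sizes: 200 Erdős–Rényi digraphs with N ≤ 12 for the
oracle cross-check (the exact oracle's symbolic factorization is
comfortable there), 20 random toy models for the screen oracle, 5+5 samples
for the cohort. Every random draw flows from an explicit seed; reruns with
the same configuration produce byte-identical outputs, which the tests
assert.

## Known limitations

- SBML import is not provided; models load from the native JSON/TSV formats.
- The context extractor is an evidence-threshold method, not a MILP; it can
  keep more reactions than a parsimony-based extractor would.
- Alternative minimum driver sets are out of scope: the canonical set
  depends on the recorded node order (sorted ids).
- Degree distributions are reported as cumulative tables against a seeded
  Erdős–Rényi reference; no power-law exponent fitting is performed.
- Flux-weighted networks, flux variability analysis and thermodynamic
  constraints are out of scope.
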