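# contarget

Network-controllability prioritization of **non-toxic anticancer metabolite
and gene targets** from context-specific genome-scale metabolic models
(GEMs).

Cancer cells rewire metabolism to sustain growth; a good metabolic drug
target is one whose removal abolishes growth in tumor-derived models while
leaving matched normal-tissue models fully functional. Constraint-based
screens (flux balance analysis, FBA) find such *lethal* perturbations but do
not rank them and say nothing about a node's role in network dynamics. This
package combines both views for a cohort of per-sample models built from
two-group expression data (cancer vs. non-cancer):

1. **Objective-dependent screens.** For every metabolite (pooled over
   compartments) remove all reactions that consume it; for every gene remove
   the reactions its loss disables under the gene–protein–reaction rules.
   A perturbation is *anticancer* if every cancer model loses viability
   (objective flux and metabolic tasks) and *non-toxic* if no non-cancer
   model does.
2. **Network construction.** From each context model derive directed
   metabolite–metabolite (MMN) and reaction–reaction (RRN) association
   networks, excluding currency metabolites (ATP, NADH, H2O, ...).
3. **Exact controllability.** For adjacency matrix A (entry (i, j) = 1 iff
   edge j→i) under dynamics x' = Ax + Bu, the minimum number of driver nodes
   equals the maximum geometric multiplicity over eigenvalues of A:

       N_D = max_λ μ(λ),   μ(λ) = N − rank(λI − A)

   A canonical minimum driver set (MDS) is read off the row reduction of
   (λ_M I − A) and certified with the Popov–Belevitch–Hautus condition
   rank([λI − A | B]) = N at every eigenvalue. Nodes whose removal raises
   N_D are *indispensable*; MDS ∪ indispensable = *controlling nodes*.
   Controlling nodes found in any non-cancer network are discarded.
4. **Prioritization.** Targets that are both anticancer non-toxic *and*
   cancer-specific controlling are ranked: indispensable-origin targets by
   total degree, driver-origin targets by normalized betweenness.

An exact rational-arithmetic oracle (characteristic-polynomial factorization
over Q; μ = (n − rank f(A))/deg f per irreducible factor f) cross-checks the
floating-point controllability path in the tests.

## Worked example

The built-in synthetic cohort plants known targets: its reference model
converts carbon A to biomass through an intermediate **X** (reactions R2A,
R2B by genes **g2a**, **g2b**) with a bypass R5 (gene g5) expressed only in
non-cancer samples. Silencing the bypass in cancer samples makes the X route
cancer-essential.

```bash
contarget run --out results/demo --seed 1
```

prints

```
reference model TOYC: 8 metabolites, 9 reactions, 6 genes
contexts: 5 cancer, 5 noncancer
antimetabolites: 7 screened, 1 pass toxicity filter
gene silencings: 6 screened, 2 pass toxicity filter
cancer-specific controlling: 1 metabolites, 2 genes
final ranked targets: 3
```

and `results/demo/ranked_targets.tsv` holds

| rank | target_id | target_type | origin | degree | betweenness | n_cancer_lethal | n_cancer_controlling |
|------|-----------|-------------|--------------|--------|-------------|-----------------|----------------------|
| 1 | g2b | gene | indispensable | 3.0 | 0.214 | 5 | 5 |
| 2 | X | metabolite | indispensable | 2.0 | 0.300 | 5 | 5 |
| 3 | g2a | gene | indispensable | 2.0 | 0.190 | 5 | 5 |

Exactly the planted targets are recovered: lethal in all 5 cancer contexts,
toxic in none of the 5 non-cancer contexts, controlling only in cancer
networks, with the highest-degree planted node ranked first. Genes such as
g1/g3/g4 (lethal but also toxic) and g5 (not lethal in cancer) are filtered
out, as is every metabolite except X.

Other entry points: `contarget synth gem|cohort|graph` write toy models,
expression cohorts, and seeded random digraphs; `build-contexts`, `screen`,
`networks`, `control`, and `rank` run individual stages. The same
functionality is available as a library (`contarget.run_pipeline`,
`contarget.exact_controllability`, ...).

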