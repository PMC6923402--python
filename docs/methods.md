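# Methods

## Model

`topcontrol` treats disease-gene prioritization as a network-controllability
problem.  A differential TF–miRNA co-regulatory network is built from the
significant DE genes, and a node's priority is the number of distinct
topological control roles it plays in that network — hub, minimum-dominating-
set (MDS) member, minimum-connected-dominating-set (MCDS) member — with
|log₂ fold change| breaking ties.  The underlying assumptions:

* regulation is directional, so **domination is directed**: a node covers
  itself and its out-neighbors (its regulatory targets).  Undirected
  domination would let a target "control" its regulator and was rejected.
* connectivity questions (largest component, MCDS connectedness) use the
  **underlying undirected graph**: regulatory cascades mix edge directions,
  and a dominating pathway is meaningful as an undirected connected
  subgraph.
* degree counts **distinct interaction partners**: a pair connected by both
  a TF→gene and a TF→miRNA record contributes one to each endpoint's degree;
  a self-loop contributes two (one in-, one out-).
* node kind (TF / gene / miRNA) is a **per-network property derived from the
  supplied edges alone** — a symbol that only appears as a regulation target
  is a gene in that network even if it is a TF elsewhere.  Conflicting
  TF-vs-miRNA evidence is an input error; a gene-vs-miRNA conflict is
  resolved by the miRNA naming convention (mir/let) or rejected.
* identifier matching is exact, case-preserving and whitespace-trimmed; no
  aliasing.  Any aliasing would silently change every overlap count
  downstream.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `de_alpha` | 0.05 | strict upper bound on adjusted p for a gene to be DE |
| `mirna_cutoff` | 0.001 | BH-adjusted enrichment threshold for miRNA inclusion |
| `enrichment_mode` | `union` | one test on targets ∪ regulators, or two separate tests |
| `hub_fraction` | 0.10 | hubs are the top ⌈fraction·N⌉ nodes by degree |
| `mds_mode` | `auto` | exact ILP up to `size_limit` nodes, greedy beyond |
| `size_limit` | 500 | largest network still solved exactly in auto mode |

**DE filtering** uses strict inequality (padj < α): "below 0.05" excludes
0.05 itself.

**miRNA enrichment.**  For miRNA *m*, the partner set P(m) is the union of
its gene targets (miRNA→gene edges) and its TF regulators (TF→miRNA edges).
The raw p-value is the inclusive upper tail P(X ≥ |P(m) ∩ DE|) of the
hypergeometric distribution with the catalog's gene/TF node set as
population.  The universe is the catalog, not the genome — no genome size
enters the workflow anywhere, so the catalog is the only defensible finite
background.  The default single **union** test is the simplest reading of
"targets and regulators are enriched"; a stricter `separate` mode (both the
target-set and the regulator-set test must pass, BH-adjusted jointly) is
available because the two readings cannot be distinguished from published
behaviour.  BH adjustment is the standard step-up procedure
(statsmodels `fdr_bh`).

**Network assembly** keeps a catalog edge iff its gene/TF endpoints are all
DE and its miRNA endpoints are all enrichment-selected; nodes are the
endpoints of kept edges, so no isolated nodes exist.  Enlarging the DE set
can only add edges (monotonicity), which the suite property-tests.

**Hubs.**  k = ⌈fraction·N⌉ with the ceiling convention, which reproduces
both published counts (⌈27.5⌉ = 28 at N = 275, ⌈46.3⌉ = 47 at N = 463).
Boundary ties are cut to exactly k, smallest identifier first, so hub sets
are size-exact and deterministic.

**MDS.**  The domination ILP — minimize Σ xᵥ subject to
xᵥ + Σ_{u∈pred(v)} xᵤ ≥ 1, x binary — is solved by HiGHS via
`scipy.optimize.milp` with lexicographic variable order, giving a proven
minimum and a reproducible (though generally non-unique) optimal set.
Nodes with in-degree 0 can only be dominated by themselves and are forced
into the set in every mode.  The greedy mode is classic set cover over
closed out-neighborhoods with the deterministic tie cascade (max new
coverage, max degree, smallest id); it is never smaller than the exact
optimum and is the fallback above `size_limit` nodes.  The 500-node default
keeps exact solving the norm at the network sizes this method targets (a
few hundred nodes).

**MCDS.**  Exact minimum connected domination is not attempted.  The
normative heuristic, fully specified here: (1) seed with the LCC node of
maximum out-degree (ties: max total degree, then smallest id); (2) while
undominated nodes remain, add the node undirected-adjacent to the current
set covering the most undominated nodes (same tie cascade), or, if no
adjacent node helps, the first step of a deterministic shortest undirected
path from the set to the nearest undominated node; (3) prune members —
scanning in ascending coverage order — whose removal preserves both
domination of the LCC and connectivity, to a fixed point.  Domination and
connectivity of the output are asserted on every run; tests additionally
check the output is never below the brute-force minimum on small graphs.

**Scoring and ranking.**  score = hub + mds + mcds flags; layer 4 is
score ≥ 1, layer 5 is score = 3 exactly.  The sort is score desc, then
|LFC| desc with LFC-less nodes (miRNAs) after the LFC-bearing rows of the
same score block, then degree desc, then id — the last two tie-breaks are
this package's own addition to make ranks total and reproducible.  Absolute
LFC is used, so a −5-fold gene outranks a +2-fold gene at equal score.

**Evaluation.**  Candidates vs an annotation list over the network node set
as universe.  Annotated identifiers not in the network are dropped before
counting — the test conditions on the constructed network.  Sensitivity
tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/N; printed percentages
round half-up.  Overlap significance is the inclusive upper tail
P(X ≥ tp); `hypergeom_upper_tail` delegates to scipy's log-space survival
function and is verified against exhaustive subset enumeration for all
populations up to 12.

## Synthetic data

The generator emulates the method's study conditions at desk scale: a
background catalog of 40 TFs, 360 genes and 12 miRNAs (~560 edges), TF
out-degrees with a Pareto tail (index 1.2, giving the right-skewed
"few master regulators" profile; max degree ≥ 5× median), 30% of gene/TF
nodes DE with padj ~ U(0, 0.05) and |LFC| ~ 0.25 + Exp(1.5) under random
sign, null genes with padj ~ U(0.05, 1).  A third of the miRNAs draw ~90%
of their partners from the DE set, so they pass the 0.001 BH cutoff by
construction; the rest draw partners uniformly.  The differential network
that construction should recover is computed by the generator's own
bookkeeping and stored as ground truth.  Disease annotations cover, at a
configurable rate (default 0.6), the planted network's likely high-priority
nodes — its top-degree decile plus its unregulated nodes (which are
necessarily dominators) — diluted with an equal number of randomly chosen
other network nodes, so that candidate evaluation faces both true signal
and noise.

What this does **not** emulate: read-count noise and DE-calling error
(expression enters as a finished DE table), database bias and literature
coverage of real interaction catalogs, identifier ambiguity, and the
community structure of real regulatory networks.  Passing tests therefore
show the machinery is correct and planted signal is recovered — not that
real catalogs at full scale would yield the same candidate quality.
Typical synthetic differential networks here have 50–80 nodes (versus a few
hundred in real use); sizes were chosen so the exhaustive oracle suites and
multi-seed recovery runs stay quick while still exercising non-trivial
topology.

## Numerical and degenerate-input choices

* Hypergeometric tails are computed in log space (scipy `sf`); k ≤ 0
  returns 1, k beyond min(K, n) returns 0.
* All tie-breaks throughout (hub boundary, greedy choice, MCDS seed/bridge,
  LCC size ties, final ranking) resolve by the documented cascades ending
  in lexicographic node id, so every operation is permutation-invariant on
  its input edge list.
* An empty differential network is a warning-bearing valid result of
  construction but an error to prioritize; an empty evaluation universe is
  an error; an annotation with no member in the universe yields
  sensitivity = None rather than a division error.
* Self-loops are retained but never alter domination (a node always covers
  itself).

## Known limitations

* The MCDS heuristic carries no approximation guarantee; only validity is
  guaranteed.  Published MCDS (and MDS) cardinalities for the original
  datasets also depend on the hosted interaction databases those analyses
  used, so set sizes are not comparable across catalogs.
* The separate-vs-union enrichment question is exposed as configuration
  rather than resolved.
* Greedy MDS above `size_limit` loses the minimality certificate (the
  `exactness` field records which path produced a result).
* Scores weight the three roles equally; no continuous centrality measures
  are used.
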