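# Methods

## Pipeline model

The package implements ligand-based polypharmacology inference for a
compound library against a panel of protein targets. The chain is strictly
feed-forward: drug-likeness filtering → similarity-based target fishing →
interaction-score confirmation → bipartite network analytics → pathway
over-representation. Each stage is a pure function of its inputs, so a rerun
with identical inputs reproduces identical artifacts byte for byte.

## Molecular representation and valence model

Molecules are heavy-atom graphs parsed from MOL V2000 / SDF. Explicit
hydrogens are folded into per-atom implicit counts derived from fixed
default valences (C=4, N=3, O=2, S=2 or 6 when the bond-order sum exceeds
2, P=3/5, halogens=1); a +1 charge on nitrogen adds one valence, any other
charge subtracts its magnitude. Aromatic-flagged bonds contribute 1.5 to
the valence sum, floored after summing, which reproduces one implicit H per
benzene carbon without Kekulé assignment. This model covers the
flavonoid/triterpenoid-like chemistry the pipeline is aimed at; elements or
valence states outside the table are rejected loudly rather than guessed.
Multi-fragment records (salts) are an error by default; an opt-in splits and
keeps the largest fragment. Stereochemistry and 3D coordinates are ignored
throughout — every downstream descriptor is topological.

## Drug-likeness

The filter demands **all five** Lipinski rules with strict inequalities
(weight < 500 Da, donors < 5, acceptors < 10, rotatable bonds < 10,
logP < 5), not the common "≤ 1 violation" relaxation. Descriptor
conventions, chosen because commercial packages define them in proprietary
and mutually inconsistent ways: acceptors = N+O atom count; donors = H on
N/O; rotatable = single, acyclic bonds between two non-terminal heavy atoms,
with amide C–N rotatable by default (a flag excludes it). logP is an
additive atom-contribution estimate over classes keyed by element,
aromaticity and heteroatom neighbourhood, with per-hydrogen terms — the
class values follow the sign and magnitude structure of published
atom-contribution schemes and are deliberately simple; any externally
computed logP column takes precedence (`logP_source` records which was
used). Summary statistics use the lower-middle median for even n and the
sample (n−1) standard deviation; both are documented because published
tables rarely state their convention.

## Target fishing

Fingerprints are multisets of atom-pair features `(type_i, type_j, d)` over
all C(n,2) heavy-atom pairs; the default atom type is element + heavy
degree, with plainer and richer schemes available to probe sensitivity.
Tanimoto similarity uses counted (minimum-multiplicity) intersection by
default — `c/(a+b+c)` — because counted pairs preserve more signal than the
set collapse; set mode is available. Edge cases are pinned: two empty
fingerprints are identical nothing (similarity 1), one empty against
non-empty is 0. Per target the aggregation over known ligands is **max**
(any sufficiently similar known ligand suffices), and a pair is retained
iff best similarity is strictly greater than the threshold (default 0.8).

## Interaction filter

Scores follow the docking-energy convention, so "stronger than the cutoff"
means score ≤ −8.0; a direction flag accommodates positive-is-better
scoring functions. The stage consumes any (compound, target, score) table —
scoring physics is out of scope by design — and a hash-based stub scorer
(deterministic in ids + seed, range [−12, −4]) stands in for tests and
demos. Missing scores are an error by default ("drop" is opt-in) because a
silently unscored candidate is the most common way such filters lie.

## Network metrics

Degree centralization `(n/(n−2))·(max k/(n−1) − ρ)` and heterogeneity
`σ_k/⟨k⟩` (population variance) follow the Cytoscape NetworkAnalyzer
conventions, since that is what readers of network-pharmacology tables
expect. Betweenness is Brandes on the whole undirected graph, normalized by
`2/((n−1)(n−2))`, computed per connected component; networks with fewer
than three nodes report zeros. Hub ranking sorts by degree, then
betweenness, then node id, making it fully deterministic. NetworkX provides
the graph container and the Brandes implementation; the test suite verifies
it against an explicit enumeration of all shortest paths on small random
bipartite graphs.

## Enrichment

The hypergeometric upper and lower tails are accumulated in log space
(log-binomials via `gammaln`, combined with `logsumexp`) so p-values of
order 1e-300 are representable; `scipy.stats.hypergeom` serves as an
independent oracle in the tests, never as the implementation. The two-sided
p is tail doubling capped at 1 — the exact construction used by common
enrichment GUIs is undocumented, so the simplest defensible rule was chosen
and a one-sided mode is exposed. The default universe is the union of
annotation genes, overridable by a universe file; no multiple-testing
correction is applied by default (the workflow filters raw p < 0.01), with
Benjamini–Hochberg available as an extra column. %associated is rounded
half-up to two decimals to match how such tables are printed.

## Synthetic data: what it emulates, and what it does not

The generator emits every input class with planted, recoverable signal:

- **Molecules** — random attachment trees over {C, N, O, S} (10–22 heavy
  atoms, carbon-biased weights), decorated with up to two ring closures and
  two bond-order upgrades under strict valence accounting. This emulates
  the size and heteroatom content of natural-product libraries, not their
  actual scaffolds, synthesizability or tautomer chemistry.
- **Reference library** — 10 targets × 2 planted actives (each a ≤1-edit
  valence-preserving perturbation of a drug-like compound, regenerated with
  fewer edits until similarity exceeds 0.8) plus 80 decoys verified at or
  below 0.8 against every compound. Planted pairs are drawn only from
  compounds that pass the Ro5 filter, so the ground truth is reachable.
- **Scores** — planted-true pairs uniform in [−11, −8], everything else in
  (−8, −4], so the score filter is exactly separating by construction.
- **Annotation** — a 200-gene universe containing the 10 target genes, 10
  pathways of 8–16 genes, one of which draws 60 % of its members from the
  query genes.

All randomness flows from named, independently derived MT19937 streams
seeded by the config, with no global state: the same seed yields
byte-identical files on any platform. Consequently, a passing end-to-end
test shows the chain's *logic* recovers planted signal exactly under
separations the generator guarantees; it says nothing about recall on real
chemistry, where actives are not perturbations of the query compounds and
score distributions overlap.

## Packaged fixtures

Three tables transcribed from a published licorice network-pharmacology
study ship with the package (checksummed TSVs): the descriptor summary of
its 181 drug-like compounds, its 49-target table (gene, protein,
betweenness, degree) and its 17-pathway enrichment table. Two derived
objects are explicitly synthetic reconstructions and are labelled as such
in their docstrings:

- `fixture_target_network()` realizes the target degree sequence on 63 compound
  nodes by the nested rule "target of degree d joins compounds 1..d". Node
  and edge counts, the full target-side degree sequence, and handshake
  quantities (1033 edges / 63 compounds → 16 targets per compound after
  truncation) are exact for *any* realization; compound-side degrees and
  path-based metrics (betweenness, centralization, heterogeneity) are
  realization-dependent and are therefore treated as plausibility numbers,
  not reproduction targets.
- `fixture_pathway_annotation()` rebuilds each pathway as its printed overlap genes
  plus synthetic padding symbols up to the back-derived size
  K = round(100·Nr/%assoc). Overlap counts and percentages are exact by
  construction; p-values are not comparable to the published ones, which
  depend on an unrecoverable annotation-release universe.

## Numerical and design choices

- Strict `>` at the similarity threshold and `≤` at the score cutoff;
  thresholds (0.8, −8.0, 0.01) are the pipeline defaults and are all
  configurable.
- Ties in enrichment ranking break by pathway name; ties in hub ranking by
  betweenness then id — every ordering in the package is total.
- Problem sizes in the test suite (molecule batches of 30–50, graphs ≤ 8
  nodes for the exhaustive betweenness oracle, full parameter sweep N ≤ 20
  for the hypergeometric oracle, 100 annotation replicates for the planted
  pathway rate) were chosen so each oracle is exhaustive or near-exhaustive
  at its scale while the whole suite stays interactive-fast.

## Known limitations

No SMILES input, no aromaticity perception beyond input flags, no 3D or
stereochemistry, no hashed fingerprints, no docking physics, no GO/term
grouping of enriched pathways. The logP estimator is a coarse additive
model intended to keep the pipeline runnable without external descriptor
software — for decision-grade work supply a measured or
vendor-computed logP column.
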