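# Methods

This note records the models, conventions and numerical choices behind
`g4causal`, in the order data flows through the pipeline.

## Coordinates and mapping rules

All in-memory coordinates are 0-based half-open; BED and bedGraph pass
through unchanged, GFF3 is converted on read ([start−1, end)) and back on
write. The midpoint of [s, e) is ⌊(s+e)/2⌋. Windows of width w centred on
position m are [m−w/2, m+w/2): length-exact and symmetric up to the
integer grid. The two window widths that matter are 150 bp (stability:
max same-strand MM% around a pG4) and 50 bp (conservation: mean phyloP
around a pG4, strand-agnostic). Region-level stability and conservation
come from the *overlapping* pG4 whose midpoint lies nearest the region
midpoint; candidates are restricted to overlapping pG4s for consistency
with the pG4-containment filter that defines the region set (a
"nearest genome-wide" mode exists for sensitivity analysis). Midpoint
ties break to the lower start coordinate, then the + strand — an
arbitrary but deterministic rule.

ATAC intensity is (per-base fragment coverage summed over the region /
region length) / mean sequencing depth. The depth denominator is not
canonical; by default it is the genome-wide mean per-base fragment
coverage computed from the supplied fragments, and callers may pass
their own. TF *occupancy* counts a TF's peaks overlapping the region;
*recruitment* is by default the total number of hits across TFs. The
alternative reading — the number of distinct TFs with at least one hit —
is implemented behind `recruitment="distinct"` rather than silently
chosen, because the two differ exactly on multi-peak regions.

Missing values (pG4 without same-strand MM% coverage, unsegmented
midpoint, uncovered phyloP window) propagate as NaN through the region
table and are dropped, with a logged count, only at discretization time:
the conditional-independence machinery needs complete cases, and
imputation would manufacture dependence.

## Discretization and sampling

Within each cell-line stratum, each numeric metric becomes High iff it
strictly exceeds the stratum median (ties at the median go Low; a
`median_ties="high"` flag flips the convention, since nothing principled
distinguishes them). Stability is instead cut at an absolute MM% ≥ 25 —
it lives on a fixed in vitro scale, unlike the per-cell-line sequencing
metrics. ChromState stays categorical. Stratified sampling is without
replacement (a bootstrap flag exists): equal allocation takes exactly k
rows per stratum, proportional takes round(k% × stratum size) with
round-half-even for platform determinism.

## Conditional-independence test

For discrete X, Y given a set S, the statistic is the conditional
Pearson χ²: the two-way χ² between X and Y computed inside each
S-configuration stratum and summed; strata with a zero margin contribute
nothing. Significance comes from a Monte-Carlo permutation test:
permuting X's values within each S-stratum preserves the conditional
margins and hence the null, and p = (1 + #{T_b ≥ T_obs})/(B + 1) with
B = 1000 by default (p-floor 1/(B+1); α defaults to 0.05 — conventional
choices, exposed as knobs).

Two implementation decisions matter:

* **Null generation.** Rather than materialising row permutations, each
  stratum's null table is drawn from the margin-preserving (multivariate
  hypergeometric) distribution — exactly the law a within-stratum
  permutation induces — which vectorises over all B replicates; 2×2
  strata collapse further to a single broadcast hypergeometric draw with
  the closed form T = N³/(r₀r₁c₀c₁)·(n₀₀−E₀₀)². Statistics are compared
  with a 1e-9 tie tolerance so exactly tied discrete values count as
  exceedances.
* **Reproducibility without order dependence.** Every (X, Y, S) test
  draws from a child RNG seeded by (master seed, CRC32 of the sorted
  variable names). Identical configurations therefore reproduce
  identical networks, and the result cannot depend on the order in which
  the algorithm happens to schedule tests — a stronger guarantee than a
  single shared stream consumed in a fixed order. The α-level decision
  path stops the Monte-Carlo loop once enough exceedances have
  accumulated to force p > α; it consumes a prefix of the same replicate
  stream, so decisions match the full p-value exactly.

Because the data are discrete, the permutation p-value is
*super-uniform* (conservative): ties in the statistic inflate p, never
deflate it. Calibration checks should therefore test the anti-
conservative direction (one-sided KS) and the empirical size; a
two-sided uniformity test will correctly reject the distribution of any
exact discrete permutation p-value at a large replicate count.

A constant X or Y yields p = 1 with a logged warning: a constant carries
no evidence of dependence.

## Structure learning

PC-stable: level-wise skeleton search with each node's adjacency set
frozen at the start of the level, so edge-removal order cannot change
the skeleton. Conditioning sets grow from ∅ up to |V|−2 by default (the
problems here have 6–12 nodes; a cap is exposed). Unshielded triples
x–z–y orient as x→z←y when z is outside the recorded separating set of
(x, y). If two v-structures claim opposite directions for one adjacency
the edge is left undirected with a logged conflict — with an exact CI
oracle this cannot occur, and under sampling noise the undirected form is
the conservative representation the consensus layer also uses. Meek's
rules R1–R4 then run to a fixed point. The independent reference for
all of this is `dag_to_cpdag`, a direct implementation of the
compelled-edge characterisation, validated in the tests against
brute-force enumeration of Markov equivalence classes; with d-separation
as the CI test, the learner reproduces it exactly on every 4-node DAG.

## Consensus and robustness

One *trial* = 10 stratified samples → 10 candidate networks. The
*average model* at threshold N keeps adjacencies present in ≥ N
candidates; a retained adjacency is directed only if a strict majority
of the candidates containing it agree on the direction (undirected
occurrences count in the denominator). The strict-majority denominator
is deliberate: counting only directed occurrences would let a single
candidate that picked up a chance false v-structure orient an edge that
nine other candidates left undirected, which is precisely the
instability the averaging exists to suppress.

*Accuracy* of a candidate is the fraction of its edges present in the
consensus; *coverage* is the fraction of consensus edges the candidate
recovers; both are averaged over candidates, compared at adjacency
(skeleton) level by default (`directed_match` tightens this), and the
consensus used is the same trial's average model at the evaluated N. A
consequence worth stating: as N grows the consensus edge set shrinks, so
mean accuracy is non-increasing and mean coverage non-decreasing in N —
these are provable identities under the definitions above and the test
suite asserts them. Robustness across the N grid is summarised by the
area under the coverage-vs-accuracy curve (trapezoidal), normalised by
the spanned accuracy range so the index is scale-free; absolute AUC
values are therefore only comparable within this convention. N is
selected as the argmin of Euclidean distance to the (1, 1) corner.

The *common network* intersects the skeletons of all trial-level
average models and records, per adjacency, the empirical frequency of
each direction (an undirected model contributes ½ to each). Resolution
keeps the strict-majority direction, leaves exact ties undirected, and
conservatively undirects any edge that would point into a protected node
— by default the stability node, since thermostability is fixed by
sequence and cannot be a downstream effect of chromatin.

## Synthetic ground truth

`default_spec()` ships the six-node network Stability→{ChromState,
nTFs, eG4s}, phyloP→{ChromState, nTFs}, ATACSig→{ChromState, nTFs},
ChromState→nTFs. Roots are Bernoulli(0.5). Binary children are logistic
in a centred parent score (±½ per binary parent, the chromatin state's
rank scaled to [−½, ½]) with effect strength 2.0 — a per-parent odds
ratio of e² ≈ 7.4, chosen once so that every edge is comfortably
detectable at the study's per-stratum sample sizes while leaving the
conditional tests non-trivial. ChromState is categorical over 8
collapsed state groups (the full 18-state vocabulary is used in the
mapping layer, but 18 levels would make the child CPT strata too sparse
to be informative at these sample sizes); its mass tilts geometrically
(strength 2.0) toward active groups as more parents are High. Default
per-stratum sizes are the three cell lines' eG4 region counts (7639,
21996, 8986), so equal-allocation k = 7000 is a genuine subsample of
every stratum. Per-stratum overrides of root distributions can emulate
cell-line heterogeneity; the defaults use none.

What the simulator does *not* emulate: spatial genomic structure in the
observational table (rows are exchangeable), continuous metric
distributions (it produces the post-discretization table directly),
missingness, and any dependence between strata. Passing tests therefore
demonstrate correctness of the machinery and recoverability under
faithful categorical data of the stated size — not that real eG4 data
satisfy faithfulness.

The toy genome generator lays candidate regions on a per-chromosome
grid (so planted pG4s, decoys and regions cannot collide), paints
non-overlapping MM%/phyloP step tracks with gaps (gaps exercise the
missing-value paths), fully segments each chromosome with 18-state
labels, and scatters ATAC fragments, TF peaks and TSSs uniformly. It is
deliberately small — every mapping rule is checked against literal
per-base scans on a thousand of these genomes within the test budget.

## Problem sizes used in the shipped checks

The acceptance suite runs the oracle-equivalence check on all 543
labelled 4-node DAGs plus 200 random 5-node DAGs; d-separation on 500
random DAGs of ≤ 6 nodes over all (X, Y, S) triples; CI calibration at
n = 500, B = 1000 over 500 replicates; mapping-oracle agreement on 1000
random toy genomes; and ground-truth recovery over 20 master seeds of
5 trials × 10 sample sets at equal-allocation k = 7000 (a scaled-down
trial count relative to the 50-trial default, which the package's own
runs use for final networks). `scripts/acceptance.py` re-runs the same
checks at moderately reduced replicate counts and reports the numbers.

## Known limitations

* The CI test is exact only conditional on the observed margins; very
  sparse S-strata (many ChromState levels × large |S|) lose power
  rather than inflating size.
* PC-type algorithms assume faithfulness and no latent confounding;
  the bidirectional regulation plausibly present between accessibility
  and chromatin state can only appear as a single directed or
  undirected edge.
* The AUC normalisation and the strict-majority orientation rule are
  package conventions; numbers produced under other conventions are not
  directly comparable.
* Real-mode inputs are read whole into memory; the intended scale is
  tens of thousands of regions, not whole-genome base-pair tracks.
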