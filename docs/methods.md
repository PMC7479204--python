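# Methods

## Model and procedure

The analysis treats a herb catalogue as a bipartite graph: side A holds
natural products (herbs), side B chemical ingredients, and an unweighted
edge records that the herb contains the ingredient.  Duplicate incidence
rows are collapsed, so multiplicity of a herb–ingredient report carries no
weight.  Degree-0 entities cannot arise from an edge-list input; the giant
(largest) connected component is extracted before any projection, with the
number and sizes of discarded components logged.  A size tie between
components is broken toward the component containing the lexicographically
smallest node identifier, making the stage deterministic on any input.

Each side is projected to a unipartite similarity network (NSN for herbs,
ISN for ingredients).  Two same-side nodes are joined iff their
opposite-side neighbour sets intersect; the edge weight is the intersection
size.  Weighted projections are the default — the shared-neighbour count is
strictly more informative than the binary "shares at least one" relation —
and every weighted consumer has an unweighted switch that binarises, so the
binary behaviour remains recoverable.  Nodes with no projection edge are
kept as isolates.

Communities are found by greedy agglomerative modularity optimisation
(Clauset–Newman–Moore).  Modularity is the weighted Newman–Girvan form
`Q = Σ_c [w_c/W − (s_c/2W)²]`; there is no resolution parameter.  Starting
from singletons, the connected community pair with maximal merge gain
`ΔQ(c,d) = w_cd/W − 2 (s_c/2W)(s_d/2W)` is merged while any gain is
positive.  Because only positive gains are accepted, the final partition is
the maximum-Q partition encountered.  Determinism without a seed: candidate
pairs are scanned in lexicographic label order and only a strictly larger
gain displaces the incumbent, so ties resolve to the smallest label pair;
the merged community keeps the smaller label; final labels are renumbered
contiguously by smallest member.  Alternative algorithms (e.g. Infomap or
walktrap run in other tools) are not reimplemented: their partitions enter
through a registry or as CSV files and are *rescored* with the same Q, so a
comparison by mean modularity across networks is on a common footing.

Community coherence is validated per annotation kind.  Set-valued
annotations (meridian and property labels for herbs, protein targets for
ingredients) are compared with the overlap coefficient
`|A∩B|/min(|A|,|B|)` by default — the most literal bounded normalisation of
a "pairwise intersection" for sets of unequal size — with Jaccard as a
configuration switch; the report records which was used.  SMILES strings
are tokenized to their set of character bigrams and compared with the Dice
index `2|A∩B|/(|A|+|B|)`; the tokenizer is a plug-in point, so a chemistry
stack can substitute fingerprint bits without changing the statistics.  A
single-character string is its own token (its bigram set would otherwise be
empty).  For every community with at least two annotated members the mean
pairwise similarity is computed; communities with fewer annotated members
are excluded and logged, and entities lacking an annotation are excluded
from that annotation's validation only, never from clustering.

The null model regroups entities uniformly at random while preserving the
multiset of community sizes; each of the 100 replicates (default)
contributes its per-community means, and all values are pooled into one
null sample.  Pooling (rather than per-replicate medians) mirrors how a
single null distribution is usually displayed alongside the observed one,
and gives the rank-sum test a stable sample size.  Observed and null
samples are compared with a two-sided Mann–Whitney/Wilcoxon rank-sum test —
unpaired, because the samples differ in size (k communities vs 100·k null
values).  The p-value is exact by enumeration when the pooled sample has at
most 12 tie-free values and otherwise uses the normal approximation with
tie and continuity corrections (delegated to `scipy.stats.mannwhitneyu`,
which implements exactly this pair of methods).

## Synthetic data

The generator emulates the *shape* of a curated herb–ingredient resource
with planted ground truth.  `n_blocks` blocks each own `herbs_per_block`
herbs, an `ingredients_per_block` ingredient pool, and signatures for every
annotation: label sets drawn without replacement from each universe and a
signature string over a 12-symbol alphabet of common SMILES characters
(chemical validity is deliberately not attempted — the tokenizer only needs
character structure).  Each herb makes `ingredients_per_herb` draws, each
from its own block's pool with probability `1 − cross_block_rate`, else
from a uniformly chosen foreign block; duplicates collapse to one edge.
Entities inherit their block signature; each label is independently
resampled uniformly from its universe with probability `annotation_noise`,
and each string character mutates with probability `string_mutation_rate`
(a resample may redraw the original symbol, so the observable mismatch rate
is `p·(1 − 1/U)`).  A single numpy Generator seeded once drives all draws
in a fixed order (block signatures, incidence, herb annotations, ingredient
annotations), so a seed determines the dataset byte-for-byte.

Defaults — 3 blocks, 20 herbs and 30 ingredients per block, 6 draws per
herb, 5% cross-block leakage, 10% annotation noise, universes of 12
meridian / 8 property / 60 target labels, 3 labels per entity, strings of
length 24 — give a small, well-separated regime: dense within-block
projections, sparse between-block edges, and annotation coherence that is
strong but noisy.  At these sizes the full pipeline runs in about a second,
and the statistical checks (recovery across 100 seeds, power across 100
seeds, type-I calibration across 500 seeds) complete in a few seconds each.

What the generator does *not* emulate: heavy-tailed ingredient frequency
distributions, overlapping ingredient pools shared by many blocks,
hierarchical or nested community structure, chemically valid SMILES, and
annotation missingness patterns.  Passing tests therefore demonstrate
correctness of the machinery and calibration of the statistics under block
structure, not performance claims on any real catalogue.

## Numerical and design choices

- Modularity of a stored partition is always recomputed from the final
  assignment (not accumulated over merges), keeping it within 1e−12 of
  `score_modularity`.
- Q of the single-community partition is exactly 0 in floating point, since
  numerator and denominator sums coincide.
- The rank-sum observed sample can be small (3 communities at the default
  configuration); with 300 pooled null values the smallest attainable
  two-sided asymptotic p is ≈ 0.003, which bounds how strongly coherence
  can be certified at that size.  The type-I rate of the full validation is
  mildly conservative there (≈ 0.03 at nominal 0.05 over 500 simulated
  independent-annotation datasets, as the calibration test measures).
- Entity identifiers are opaque strings; side membership is tracked by
  structural tags, never by string content.
- The run report echoes the configuration and seed; reruns with the same
  config and seed produce byte-identical artifacts, with wall-clock fields
  (`started_at`, `finished_at`, `elapsed_s`) the only varying entries.

## Limitations

- Greedy agglomeration is a heuristic: on graphs whose optimum is not
  reachable by pairwise merges it returns a lower-Q partition (the test
  suite checks optimality only on small instances constructed to be
  agglomeration-reachable, and upper-bounds Q by exhaustive search
  elsewhere).
- No multiple-testing correction is applied across the four annotation
  kinds; all raw p-values are reported and users may correct downstream.
- Overlapping (soft) communities, Markov clustering, Louvain/Leiden, and
  tripartite extensions are out of scope.
- The permutation null conditions on the detected partition's sizes; it
  does not account for the fact that the partition was itself optimised on
  the same graph (the annotations, however, are never used in clustering,
  which is what the test relies on).
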