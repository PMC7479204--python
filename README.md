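# tcmnet

Network-pharmacology analysis of traditional Chinese medicine (TCM) herb
catalogues.  Curated resources such as TCMID list which chemical ingredients
each natural product (herb) contains; `tcmnet` models this relation as a
bipartite network, projects it onto either node set, finds communities by
greedy modularity optimisation, and tests whether those communities are
coherent with respect to external annotations — the herbs' traditional
meridian and property classifications, and the ingredients' SMILES strings
and protein-target sets.

The package is aimed at computational pharmacologists and systems biologists
who have (or can export) a herb–ingredient incidence table plus annotation
tables, and want a reproducible, tested pipeline from edge list to
statistical validation.  A planted-block synthetic generator makes every
stage testable without any database download.

## Method

1. **Bipartite graph.**  Herbs and ingredients form the two sides of a
   bigraph; an edge means "herb contains ingredient".  After removing
   disconnected parts, the giant component is kept.
2. **Projection.**  The herb-side projection (NSN, natural-product
   similarity network) joins two herbs iff they share at least one
   ingredient, with edge weight `w(u,v) = |N(u) ∩ N(v)|`, the number of
   shared ingredients; symmetrically the ingredient-side projection (ISN).
3. **Communities.**  Clauset–Newman–Moore greedy agglomeration maximises
   the Newman–Girvan modularity

       Q = Σ_c [ w_c / W − (s_c / 2W)² ]

   where `W` is total edge weight, `w_c` the intra-community weight and
   `s_c` the community strength.  The implementation is deterministic
   (lexicographic tie-breaks) and alternative partitioners can be plugged
   in and compared by mean Q.
4. **Validation.**  For each annotation kind, the mean pairwise similarity
   within each community (overlap coefficient `|A∩B|/min(|A|,|B|)` for
   label/ID sets, Dice index `2|A∩B|/(|A|+|B|)` on character-bigram sets
   for SMILES strings) is compared with a null built from 100 random
   regroupings that preserve community sizes, using a two-sided Wilcoxon
   rank-sum test.

The core computations are exposed as scikit-learn style estimators
(`BipartiteProjection`, `FastGreedyCommunities`, `CoherenceValidator`);
the graph-level functions wrap them.

## Worked example

```python
import tcmnet as t

cfg = t.SyntheticConfig(seed=1)           # 3 planted blocks, 60 herbs, 90 ingredients
inc, anns, truth = t.generate_dataset(cfg)

gc  = t.giant_component(t.build_bipartite(inc))
nsn = t.project(gc, "herb")
part = t.fast_greedy(nsn)
print(part.n_communities, round(part.modularity, 4))

rep = t.validate(part, anns["meridian"], n_replicates=100, seed=1)
print(round(rep.observed_median, 3), round(rep.null_median, 3), f"{rep.p_value:.3g}")
```

prints

```
3 0.5668
0.844 0.501 0.00291
```

The three planted herb blocks are recovered as three communities with
modularity 0.57; herbs in the same community share 84% of their meridian
labels on average (median over communities), against 50% for random groups
of the same sizes — a significant excess (p ≈ 0.003, Wilcoxon rank-sum).

The same analysis runs from the shell:

```sh
tcmnet generate --seed 1 --outdir data/
tcmnet project --input data/incidence.tsv --side herb --out nsn.tsv
tcmnet cluster --graph nsn.tsv --out nsn_partition.csv
tcmnet validate --partition nsn_partition.csv --ann data/meridian.tsv \
    --kind label_set --reps 100 --seed 1 --out validation.json
tcmnet pipeline --seed 1 --outdir run/      # everything at once
```

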