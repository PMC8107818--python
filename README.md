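# qenp — quantity-effect weighted network pharmacology

`qenp` implements a weight-coefficient network-pharmacology workflow for
multi-component botanical drugs. Instead of treating every ingredient
equally, each compound gets a *quantity-effect* weight

    ci = relative_content_pct * oral_bioavailability

which is propagated through the compound → target → pathway chain: target
weights `ti` sum the `ci` of the compounds hitting each protein, pathway
weights sum the `ti` of each gene set's scored members, and enrichment
results are re-ordered by pathway weight so that high-content, well-absorbed
components drive the ranking.

Supporting stages shipped alongside the weight engine:

- **compound_table** — GC-MS composition tables and Kovats retention
  indices from an n-alkane ladder (C8-C40, linear interpolation, no
  extrapolation). A 19-compound composition table is packaged as a demo
  input (`qenp/data/compound_composition.tsv`).
- **target_sets** — case-insensitive gene-symbol lists, deduplication,
  and drug ∩ disease intersection.
- **network_analysis** — bipartite compound-target networks, scored PPI
  edge lists (STRING-export compatible), score-threshold filtering
  (default ≥ 0.400), raw degree and betweenness centrality, and hub
  selection by strict comparison against the mean degree.
- **enrichment** — self-contained over-representation analysis over GMT
  collections: upper-tail hypergeometric p-values, Benjamini-Hochberg
  adjustment, size gates [5, 500], and before/after rank-shift reporting.
- **clinical_scoring** — a colitis disease-activity-index rubric: three
  0-4 component scores averaged into a DAI in [0, 4].
- **fixtures** — seeded synthetic generators (compound tables, OB tables,
  bipartite maps, disease lists, gene sets with a planted pathway, scored
  PPI edges) so the whole pipeline is testable offline.

## CLI

One subcommand per stage; every run writes its stage TSVs plus a
machine-readable `<stage>_manifest.json` into `--outdir`. A flat YAML
config (`--config`) can supply any flag; explicit flags win.

```sh
qenp fixtures make --seed 7 --outdir ws           # synthetic demo workspace
qenp ri        --compounds ws/compounds.tsv --ladder ws/alkane_ladder.tsv --outdir out
qenp weights   --compounds ws/compounds.tsv --ob ws/ob.tsv \
               --target-map ws/compound_targets.tsv --outdir out
qenp intersect --drug ws/universe.txt --disease ws/disease_targets.txt --outdir out
qenp network   --target-map ws/compound_targets.tsv --outdir out
qenp ppi       --edges ws/ppi_edges.tsv --outdir out        # threshold 0.400
qenp enrich    --hits out/intersection.txt --gmt ws/gene_sets.gmt \
               --universe ws/universe.txt --weights out/target_weights.tsv --outdir out
qenp rerank    --enrichment out/enrichment.tsv --outdir out # rank-shift table
qenp dai       --observations obs.tsv --outdir out
```

Exit codes: 0 success, 2 validation/format error, 1 runtime error. Runs
are deterministic: identical inputs and flags produce byte-identical
outputs.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (exhaustive
hypergeometric enumeration, hand step-up BH, simple-path betweenness
tallies), hypothesis property tests for the analytic invariants, and a
100-replicate planted-pathway recovery simulation.

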