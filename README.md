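# cladestore

A taxonomy-indexed metadata engine for eukaryotic taxa and genome
assemblies. It is aimed at people coordinating or planning genome
sequencing at scale — across projects, clades or whole target lists —
who need one queryable view over heterogeneous species and assembly
metadata: genome sizes and C-values, chromosome numbers, assembly spans
and N50s, assembly levels, sequencing statuses and project target
lists.

The engine has four parts:

1. **Taxonomy backbone.** An NCBI-style taxdump (`nodes.dmp`,
   `names.dmp`) is loaded into one document per taxon, each carrying
   its ordered lineage ⟨parent, …, root⟩ with ranks and depths, so
   clade-scoped queries become lineage-membership tests. Taxa missing
   from the backbone can be grafted at the nearest resolvable anchor
   rank (genus, family, …). Assemblies form a second index, one
   document per assembly, inheriting the owner's lineage.
2. **Declarative import.** Each data source is a delimited table (one
   taxon or assembly per row) plus a YAML spec declaring column →
   attribute mappings, transforms (e.g. picograms → base pairs at
   1 pg = 0.978 × 10⁹ bp), constraints, and how rows are matched to
   taxa. Unmatched or invalid rows go to an exceptions file; fuzzily or
   indirectly matched rows go to a review file.
3. **Fill.** Raw values are reduced to one reported value per taxon by
   ordered summary rules (min/max/mean/median/mode, enum- or
   source-priority). Missing values are then inferred on the tree: a
   bottom-up pass gives internal nodes the median (numeric) or mode
   (categorical) of their children's values, and a top-down pass copies
   the nearest informative ancestor's value to the remaining nodes.
   Every value carries traffic-light provenance: green = direct,
   orange = from descendants, red = from an ancestor.
4. **Search and reports.** Queries are conjunctions of taxon terms
   (`tax_tree`, `tax_name`, `tax_eq`, `tax_rank`, `tax_depth`,
   `tax_lineage`) and attribute comparisons
   (`assembly_span > 500000000`, `assembly_level>=chromosome`,
   `min(assembly_span)>2e9` on summary ranges, `length(long_list)>1` on
   list attributes), with comma-OR and `!` negation. Results format as
   TSV/CSV/JSON in summary, tidy or raw layouts. Five report types
   aggregate results: per-rank counts, subset ratios, histograms,
   scatter/heatmaps, and annotated subtrees exportable as Newick or
   PhyloXML.

## Worked example

Everything below runs offline against generated fixtures (500 species,
~750 taxa, seeded):

```sh
cladestore synth --out fx --n-species 500 --seed 7
cladestore --store store.json init --taxdump fx/taxdump
cladestore --store store.json index --dir fx/data
cladestore --store store.json fill
```

```text
INFO loaded 748 taxa into store.json
INFO indexed 950 rows from 5 files
INFO fill chromosome_number: 647 estimates written
INFO fill genome_size: 605 estimates written
```

Count species whose reported genome size (direct or inferred) exceeds
2 Gb, then list family-level values:

```sh
cladestore --store store.json count "tax_rank(species) AND genome_size>2000000000"
# 121
cladestore --store store.json search "tax_rank(family) AND genome_size" \
    --fields genome_size --format tsv | head -5
```

```text
taxon_id  scientific_name  rank    genome_size
31        Family31         family  1386705812.0606914
32        Family32         family  1623116083.071581
33        Family33         family  1220119744.1083803
34        Family34         family  986095542.3735468
```

The family rows are descendant-derived estimates (medians over each
family's measured species); `search --mode tidy` adds the provenance
column. Assembly-index queries return one row per assembly — here, the
number of assemblies meeting the reference standard of contig N50 >
1 Mb and scaffold N50 > 10 Mb:

```sh
cladestore --store store.json count \
    "contig_n50>1000000 AND scaffold_n50>10000000" --index assembly
# 69
```

Tree reports export annotated subtrees:

```sh
cladestore --store store.json report tree \
    --query "tax_tree(2) AND tax_rank(family)" --export newick
# ((((Family31)Order13,(Family32,Family33,Family34,Family35)Order14,...
```

## Layout

```
src/cladestore/
  taxonomy.py   backbone store, lineages, insertion, name lookup
  ingest.py     YAML import specs, transforms, taxon matching, indexing
  fill.py       summary statistics and two-pass tree propagation
  query.py      search grammar parser, evaluator, output formats
  report.py     xPerRank / arc / histogram / scatter / tree reports
  synth.py      seeded synthetic taxonomies, attribute and assembly tables
  cli.py        init / index / fill / search / count / record / report / synth
```

See `docs/methods.md` for the model, parameter and design notes.
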