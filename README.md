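# blisterome

Tools for turning a phenotype screen's gene lists into an interaction
network and asking whether the hits hang together more than chance allows.

The motivating setting is a genome-scale *Drosophila* RNAi wing screen:
knockdown lines are scored for wing-blister phenotypes (failure of adhesion
between the dorsal and ventral wing epithelia), hits are merged with
literature-curated blister genes, and the combined candidate set is placed
into a protein/genetic interaction network that is enriched with
*interologs* — interactions inferred from the physical interactions of the
genes' human orthologues. The package covers each analysis stage as a
library module plus a thin CLI, and ships a synthetic-data generator that
emulates the statistical structure of the real inputs (screen error rates,
GO annotation spread, planted network modules, many-to-many orthology,
disease tables), so the whole pipeline is testable offline.

## What it computes

* **Gene-list algebra** (`phenotype_screen`) — merging phenotype
  categories, combining screen and literature lists, per-phenotype line
  fractions, and literature recovery: with lists of sizes $n_a$, $n_b$
  sharing $s$ genes, the union is $n_a + n_b - s$ and recovery is
  $100\,s/n_a$ per cent over the screened portion of the literature list.
* **GO enrichment** (`go_enrichment`) — the EASE score, a conservative
  one-sided Fisher exact test on the $2\times2$ table (overlap $k$, list
  $n$, term background count $K$, universe $N$) with the overlap
  decremented by one:
  $p = P[X \ge k-1]$, $X \sim \mathrm{Hypergeom}(N, K, n)$,
  corrected per namespace by Benjamini–Hochberg; plus Cohen's-kappa
  functional classification of genes by annotation co-occurrence.
* **Semantic term reduction** (`go_semantics`) — information content
  $\mathrm{IC}(t) = -\log f(t)$ from ancestor-propagated annotation
  frequencies, Resnik similarity $\mathrm{sim}(t_1,t_2) =
  \mathrm{IC}(\mathrm{MICA})$, greedy removal of redundant enriched terms
  above a normalised similarity cutoff $C$ (default 0.5), and the
  top-3%-similarity term graph.
* **Interolog projection** (`ortholog_projection`) — translation of human
  physical interactions $(H_1, H_2)$ into fly pairs $(A, B)$ for all
  $A \in \mathrm{orth}^{-1}(H_1)$, $B \in \mathrm{orth}^{-1}(H_2)$,
  discarding projected self-pairs (apparent homodimers that are artefacts
  of heterodimerisation between co-orthologues), then merging native and
  projected edges into one simple graph with evidence-kind sets.
* **Network significance** (`network_analysis`) — induced-subgraph
  connectivity (mean local clustering coefficient, connected-node count,
  average neighbours per node, non-trivial components) against a Monte
  Carlo null of equally sized random gene sets, with fold-over-null-median,
  a one-sided one-sample Wilcoxon signed-rank p, a calibrated empirical
  tail probability, and a Kolmogorov–Smirnov normality check on the null.
* **Disease mapping** (`disease_mapping`) — joining human orthologues to
  OMIM/KEGG-style disease records, organ-system share distributions and
  per-gene multiplicity histograms.

## Worked example

Plant a densely connected 358-gene module (within-module edge probability
0.05) in a 1600-gene universe over a sparse background (0.002), then ask
whether the module's connectivity exceeds 100 random 358-gene sets:

```python
from blisterome import synthetic_data as syn
from blisterome.network_analysis import (connectivity_stats, induced_network,
                                         monte_carlo_null, significance)

universe, dag, annotations = syn.generate_universe(syn.UniverseSpec(n_genes=1600, seed=1))
genes = sorted(universe.gene_ids())
module = frozenset(genes[:358])
network = syn.generate_network(universe, syn.NetworkSpec(
    background_edge_prob=0.002, module_edge_prob=0.05,
    module_genes=module, seed=2))

observed = connectivity_stats(induced_network(set(module), network))
null = monte_carlo_null(universe.gene_ids(), network, set_size=358, n_iter=100, seed=3)
for stat, res in significance(observed, null).items():
    print(f"{stat:24s} fold={res.fold_over_median:6.2f}  p={res.p:.2e}")
```

prints

```
clustering_coefficient   fold=  3.34  p=1.98e-18
n_connected_nodes        fold=  1.63  p=1.96e-18
avg_neighbors            fold=  7.04  p=1.98e-18
```

i.e. the planted module clusters 3.3× more, connects 1.6× more of its
genes, and has 7× more neighbours per node than the median random set, far
beyond what any of the 100 null draws achieves. The same computation is
available from the shell (`blisterome mc-null …`), and `blisterome run-all
--seed 1 --outdir out` runs the full six-stage pipeline on a synthetic
bundle, writing per-stage TSV/JSON/GraphML outputs and a run manifest.

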