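# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the package's known limitations.

## Gene-list statistics

Gene identity is the fly gene identifier; RNAi-line multiplicity is kept as
per-gene metadata (`n_lines`) but all downstream counting is over genes.
Printed percentages use half-up rounding (one decimal for phenotype
fractions, integer for recovery), matching the convention of published
summary tables rather than Python's banker's rounding. Literature
recovery divides detected literature genes by the literature genes that
were actually screened, not the whole curated list; a literature list with
no screened member has no defined recovery and raises.

## Enrichment: EASE, Fisher, Benjamini–Hochberg

Both the plain one-sided Fisher exact test and the EASE variant (overlap
decremented by one before taking the hypergeometric upper tail) are
implemented; EASE is the default because it is deliberately conservative
for small overlaps — a single-gene overlap carries no evidence (p = 1).
Terms with fewer than two target genes are not tested. Annotations are
propagated to `is_a` ancestors before counting, and the correction is
applied within each GO namespace separately, since each namespace is an
independent family of hypotheses. Tail probabilities come from
`scipy.stats.hypergeom` and the step-up correction from
`statsmodels.stats.multitest`; the unit tests check both against
enumeration oracles.

Functional classification uses Cohen's kappa between binary term vectors
over a shared term universe. Degenerate vector pairs (chance agreement
exactly 1) are defined as kappa 0. Clustering is greedy seed-and-merge:
gene pairs at kappa ≥ 0.35 seed groups, and groups merge while any two
share at least half of the smaller group. These two thresholds are
declared approximations of the fuzzy-clustering heuristics of the DAVID
service, whose exact internals are unpublished; the module-count outputs
are therefore structural, not reference values.

## Information content, Resnik similarity, term reduction

IC is corpus-based: the frequency of a term is the fraction of corpus
genes annotated to it or any descendant, relative to the genes under the
namespace root, in natural-log units, so IC(root) = 0 and IC is monotone
non-decreasing towards the leaves. The default corpus is the screened
background universe rather than a whole-genome annotation set — the
enrichment background and the similarity corpus then agree; any
`AnnotationSet` can be substituted. Terms with no annotated gene carry an
infinite sentinel and never win a MICA search.

Resnik similarity is the IC of the most informative common ancestor.
Because raw Resnik is unbounded while the reduction cutoff C lives on
[0, 1], similarities are normalised by the maximum finite corpus IC before
comparison with C. Reduction is iterative and greedy: repeatedly take the
most similar surviving pair above C and drop the member with the larger
adjusted p-value (ties: the less informative term, then the
lexicographically larger id). This is a declared approximation of full
dispensability optimisation; the tests verify that the survivor count
matches exhaustive minimum-loss reduction on small inputs and that no
surviving pair exceeds C. The term graph keeps the
⌈top_fraction · n_pairs⌉ strongest pairwise similarities as edges
(default 3 %), with deterministic lexicographic tie-breaking, and
annotates nodes with IC and adjusted p so that renderers can map them to
size and shading.

## Interolog projection

Only *physical* human interactions are projected by default: genetic
interactions reflect pathway logic that does not transfer across species
edge-by-edge (a flag widens the kinds). For a human edge (H1, H2) every
fly pair in reverse(H1) × reverse(H2) is emitted except self-pairs:
when H1 and H2 are both co-orthologues of one fly gene, the projected
"homodimer" is usually an artefact of heterodimerisation between
duplicated human genes, so such records are dropped and counted.
Human self-loops are skipped; edges with an unmapped endpoint are counted
as untranslatable rather than fatal, because real orthology tables are
incomplete. Deduplication over unordered fly pairs happens after
projection, which is order-independent. Merging native and projected
records yields a simple graph whose edges carry the set of contributing
evidence kinds.

## Network connectivity and the Monte Carlo null

The induced network of a candidate set drops isolated candidates, matching
how interaction databases display gene-set networks (genes without any
reported interaction in the set do not appear). The three tested
statistics are the mean Watts–Strogatz local clustering coefficient (nodes
of degree < 2 contribute zero to the mean), the connected-node count, and
the average neighbours per connected node (2|E|/n). The count of
components of size ≥ 2 is computed and reported alongside but is not a
default test statistic: for an enriched network more connected nodes and
neighbours is "better", whereas the component count can move either way as
fragments merge.

The null samples `set_size` genes uniformly without replacement from the
full supplied universe — including genes with no interactions — and
recomputes all statistics per iterate (defaults: 358 genes, 100 iterates).
Significance reports, per statistic: the fold of the observed value over
the null median (flagged when the median is zero) and a one-sided
one-sample Wilcoxon signed-rank p-value of (null − observed), exact when
n ≤ 25 with untied non-zero differences, otherwise the tie-corrected
normal approximation with zero-dropping and continuity correction. A
one-sample Kolmogorov–Smirnov check against a fitted normal documents the
null's non-normality.

**Limitation — the Wilcoxon p is anti-conservative for this design.**
The one-sample test treats the observed value as a fixed reference, but
when the candidate set is itself exchangeable with the null draws the
reference is random, and the test detects *any* displacement of that draw
from the null median: its one-sided rejection rate at α = 0.05 tends
towards 0.5 as the number of Monte Carlo iterates grows (measured: ≈ 35 %
at 30–40 iterates). Tiny Wilcoxon p-values therefore mainly certify that
the observed value sits outside the bulk of the null sample; they are not
a calibrated false-positive rate for "this gene set is a module". For a
calibrated decision use `SignificanceResult.p_empirical`, the permutation
tail probability (1 + #{null ≥ observed})/(n_iter + 1), which is valid
(conservative under ties) and whose type-I control is property-tested.
Both numbers are reported so the fold/Wilcoxon presentation stays
comparable with the screening literature while the empirical p carries the
inference.

## Synthetic data

The generators emulate the study conditions the analysis assumes, with one
explicitly seeded `numpy` Generator per call and no global state:

* **Universe** — default 1573 genes (the screened-library scale); three
  namespaces, each a layered DAG (default 40 terms over depth 4, one root,
  every non-root term with ≥ 1 parent in the level above, occasional
  multi-parents). Direct annotation probability halves per depth level
  from `annotation_rate` (default 0.06) at depth 1, giving the few-large /
  many-small geometric term-size spread that makes IC non-degenerate;
  every gene reaches the namespace roots after propagation.
* **Screen** — true hits retained with probability 1 − FN (default
  FN = 0.29), non-members admitted with probability FP (default 0.07),
  labels "blister"/"burned" assigned half-and-half without meaning.
* **Network** — Erdős–Rényi background (default edge probability 0.002)
  with a planted module whose internal pairs connect at 0.05; at the
  default 1600-gene/358-module scale this reproduces "tightly connected
  candidate set over sparse background" without mimicking any real
  topology (no degree heavy tails, no hubs).
* **Orthology** — zero-inflated shifted Poisson: a fly gene is unmapped
  with probability 0.115, otherwise maps to 1 + Poisson(λ) human genes
  with λ set so the unconditional mean is 2.45 orthologues/gene (hence
  ≈ 877 pairs for 358 genes); human partners are drawn from a shared pool
  so co-orthology arises.
* **Disease table** — genes disease-related with probability 190/877,
  1 + Poisson(0.4) diseases each, organ systems drawn from 11 categories
  with 1/rank weights so early categories dominate.

What passing tests on this data do **not** show: robustness to real GO
topology (depth 15+, part_of/regulates edges), to scale-free interaction
networks with study-bias hubs, to identifier aliasing noise, or to
correlated annotation/interaction structure (here annotations and edges
are independent unless `plant_enrichment` is used). The generators test
the algebra and the statistics, not database quirks.

## Numerical and interface conventions

Identifiers are canonical case-sensitive strings; alias resolution is a
reader concern. All tabular I/O is headered TSV; the ontology travels as
a minimal OBO subset (`is_a` only) parsed via obonet with cycle rejection;
graphs export to SIF and GraphML. Empty-input conventions: empty graph →
all-zero statistics; empty enrichment input → empty output; empty disease
table → error for distributions (no denominator). The pipeline derives a
31-bit per-stage seed from the top-level seed via FNV-1a hashing of
`"{seed}:{stage}"`, so stages are individually reproducible; two runs with
identical configuration produce byte-identical stage outputs.

Default problem sizes in the test and acceptance runs (1600-gene universe,
358-gene module, 100 Monte Carlo iterates; 200-seed calibration sweeps at
39 iterates) were chosen as the smallest scales at which the study-scale
expectations (binomial/Poisson tolerances, null separation) are stable;
larger runs change timings, not conclusions.
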