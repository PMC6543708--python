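# Methods

## Unified pan-prokaryote annotation

The annotation model treats a gene symbol as a cross-organism concept:
records `(organism, gene, term)` are pooled over bacteria and archaea after
case-folding symbols and applying an optional alias → canonical synonym map
(resolved transitively; cycles are rejected). For each surviving pair the
relative frequency is

    rel_freq(g, t) = n_pair / n_gene,

where `n_gene` counts organisms with at least one annotation record for `g`
and `n_pair` counts organisms whose records contain `(g, t)`. Organism
membership of a gene is operationalized through its annotation records —
the corpus carries no genome-content information independent of
annotation, so "organism contains the gene" means "organism annotates the
gene at least once".

Pairs strictly below the gene-specific median of `rel_freq` are excluded.
The median uses the midpoint convention for even-length distributions and
exclusion is strict (`<`), so a gene with a single pair — or with all pairs
at one frequency — keeps its annotation. This removes associations reported
by only a small minority of the organisms carrying a gene, which are
dominated by annotation depth of heavily studied taxa rather than by
biology.

Ancestor propagation (the GO true-path rule) is applied **after** the
median filter, and only within each term's namespace. Filtering raw pairs
first is a deliberate ordering: propagation multiplies every specific
annotation into its ancestor chain, which would inflate ancestor
frequencies and drag each gene's median toward 1, eliminating legitimate
specific annotations. Propagation defaults to on, since the enrichment
background needs ancestor-closed term sets; it can be disabled.

## Ontology handling

The OBO loader keeps obsolete terms in the term table (so stale accessions
still resolve, as do `alt_id` secondaries) but excludes them from the
graph. `is_a` edges are always traversed; `part_of` traversal is a
load-time flag, default on, matching common GO practice — both behaviors
are exposed because either convention is defensible. Validation enforces
acyclicity (one offending cycle is reported), known non-obsolete edge
endpoints, and `is_a` staying within a namespace.

## Alignment filtering

Coverage is the aligned-span fraction of the full sequence computed from
coordinates, `(end − start + 1) / length`, not from the alignment length,
which counts gap columns. Hits are kept when query coverage ≥ 0.90 AND
subject coverage ≥ 0.50 AND e-value ≤ the user-supplied ceiling; the
boundary is inclusive because the exclusion rule is "coverage *lower than*
the threshold". The e-value ceiling has no default — it is a per-analysis
choice and the CLI makes it mandatory for BLAST input. Best-hit selection
per query orders by (e-value asc, bit score desc, subject accession asc);
the two tie-breaking keys make the pipeline invariant to input row order.
Input must be the 14-column tabular dialect (`std qlen slen`); a 12-column
file is rejected with the exact `-outfmt` string to re-run, since coverage
cannot be computed without lengths.

## Enrichment statistics

The test is the one-sided hypergeometric tail (Fisher exact,
over-representation side), delegated to `scipy.stats.hypergeom.sf`, which
sums the tail stably; the suite pins it against exact integer enumeration
for all N ≤ 25 at 1e-12.

Terms are tested only inside the informativeness window
`min_term_genes ≤ K ≤ max_term_fraction · N` (defaults 2 and 0.25):
singleton terms cannot be meaningfully over-represented and root-like terms
annotating a quarter of the background carry no interpretive value. Both
bounds are configurable.

Two corrections are reported per term. The empirical p-value resamples
`n_resamples` null queries (uniform, without replacement) and uses add-one
smoothing, `p_emp = (1 + #{k* ≥ k_obs}) / (1 + R)`, so it is never zero —
standard permutation-test practice, at the cost of a floor of `1/(R+1)`.
The q-value is the Benjamini–Hochberg step-up applied to the empirical
p-values across tested terms; significance defaults to `q_bh ≤ alpha`
(switchable to `p_emp`). The resampling null doubles as a distribution-free
cross-check of the parametric tail: the suite verifies every term's
empirical p within 3 Monte-Carlo standard errors of the exact tail at
50,000 resamples.

Null calibration of a discrete test deserves a caveat: because the
hypergeometric support is a finite lattice, `P(p_raw < alpha)` under a
uniform null equals the largest achievable tail probability below `alpha`,
which at a 200-gene universe and 30-gene queries averages ≈ 0.03 rather
than 0.05. The raw p-values are therefore conservative (never
anticonservative); exact lattice computation, not a simulation artifact,
explains observed null rejection rates below nominal in the suite and the
acceptance report.

Permutation is vectorized: null queries are drawn as the `n` smallest of
`N` random keys per replicate and overlaps computed by a membership-matrix
product, chunked to bound memory; the generator is seeded, so all
enrichment output is byte-reproducible.

## Gene prioritization

"Participation in topologically distinct parts of the graph" is
operationalized as the ancestry antichain of the significant terms: of
every ancestor–descendant pair the more specific descendant survives
(invertible via a flag; specific terms carry more information, which is why
keep-descendant is the default). Genes are scored by the number of
antichain terms whose *hit genes* contain them — query-side evidence, so
the ranking reflects the analyzed sample rather than the full annotation.
Ties break by the larger sum of −log10(p_emp) over supporting terms, then
lexicographically. An empty significant set yields an empty ranking, not an
error.

## Synthetic data

The generators emulate the four pipeline inputs with planted truth:

- **Ontology** — per namespace a rooted DAG grown by attaching each new
  term to 1..`max_parents` earlier terms (acyclic by construction); a
  `min_root_children` knob forces disjoint root branches for tree-shaped
  (`max_parents=1`) prioritization fixtures.
- **Corpus** — each gene lives in ≥ 2 of 20 organisms and carries 1..3 core
  terms per namespace annotated in *every* organism carrying the gene
  (rel_freq exactly 1), plus noise pairs annotated in a single organism.
  Noise is capped at the core-pair count, which guarantees the gene median
  separates cores from noise, so the planted noise set is provably the
  median-excluded set. Defaults (20 organisms, 200 genes, 60 terms per
  namespace) keep the suite fast while giving ~40 informative terms.
- **BLAST rows** — spans are integer-constructed against the rational
  thresholds 9/10 and 1/2, so pass/fail labels are unambiguous; every tenth
  passing row sits exactly on a coverage boundary to pin the inclusive
  boundary semantics. E-values are log-uniform on either side of the
  cutoff.
- **Queries** — an `effect_size` fraction drawn from planted-term gene
  sets, the rest uniform; `effect_size=0` gives a null query.

What the fixtures do **not** emulate: real annotation is not bimodal in
relative frequency (core pairs at exactly 1.0 are an idealization that
makes median-filter truth exact), gene symbols carry no real synonym
structure, BLAST scores are not coupled to identities or lengths, and no
sequence-level realism is attempted. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under controlled
conditions, not performance on real SwissProt-derived corpora.

## Problem sizes and numerical choices

The suite and the acceptance script use: exhaustive hypergeometric
verification for all N ≤ 25 (≈ 44,000 tuples); permutation agreement at
50,000 resamples on a 300-gene universe; 200 null queries for calibration;
100 seeded planted-term runs (universe 500, term size 40, query 30, effect
0.8) and 50 seeded hub runs at 2,000 resamples each, where only the
*ranking* of empirical p-values matters and 2,000 resamples resolves it;
pipeline demonstrations at 10,000 resamples (the default). BH adjustment is
implemented directly (sorted step-up with a reverse cumulative minimum) and
cross-checked against `statsmodels.multipletests(method="fdr_bh")`.

Degenerate inputs are defined rather than accidental: `k = 0` gives
`p_raw = p_emp = 1`; a query fully outside the universe is an explicit
error while partial overlap drops the outside genes with a report; an
unresolvable term accession goes to a rejects list, not an exception; an
empty corpus is an explicit error. Run reports and logs contain no
timestamps, so identical configurations produce byte-identical output trees.

## Known limitations

- Symbol-level clustering stands in for sequence-level clustering of
  orthologs; genes that share a symbol across organisms are assumed to be
  the same concept, and divergent naming splits true orthologs.
- The raw test is conservative on small universes (discreteness, above);
  the empirical p inherits a resolution floor of `1/(n_resamples + 1)`.
- Prioritization scores only the enriched antichain; genes whose breadth
  lies outside the significant set score 0 and are omitted.
- The unified-annotation cache stores raw retained pairs; reloading always
  re-propagates, so a cache written with propagation disabled reproduces
  the propagated maps on load.
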