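"""Master-regulator gene prioritization over enriched GO terms.

Genes participating in many topologically distinct parts of the ontology
graph are candidate drivers of community features. "Topologically distinct"
is operationalized as the ancestry antichain of the significant terms: for
every ancestor-descendant pair among them only the more specific descendant
survives, so no two scored terms are related by ancestry. Each gene is then
scored by the number of surviving terms whose query-side hit genes include
it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .enrichment import EnrichmentParams, EnrichmentResult, significant
from .ontology import OntologyGraph


@dataclass
class GeneScore:
    gene: str
    score: int
    support: tuple[tuple[str, float], ...]  # (term_id, p_emp) pairs
    sum_neglog10_p: float
    rank: int = 0


def prune_redundant_terms(
    enriched_terms: "list[str]",
    ontology: OntologyGraph,
    keep: str = "descendant",
) -> list[str]:
    """Reduce a term list to an ancestry antichain.

    With ``keep='descendant'`` (default) the more specific member of every
    ancestor-descendant pair survives; ``keep='ancestor'`` inverts this.
    All terms must belong to a single namespace.
    """
    if keep not in ("descendant", "ancestor"):
        raise ValueError("keep must be 'descendant' or 'ancestor'")
    terms = list(dict.fromkeys(enriched_terms))
    if not terms:
        return []
    namespaces = {ontology.namespace_of(t) for t in terms}
    if len(namespaces) > 1:
        raise ValueError(
            f"enriched terms span multiple namespaces: {sorted(namespaces)}"
        )
    term_set = set(terms)
    pruned = []
    for t in terms:
        related = ontology.descendants(t) if keep == "descendant" else ontology.ancestors(t)
        if not (related & term_set):
            pruned.append(t)
    return pruned


def score_genes(
    pruned_terms: "list[str]",
    results: "list[EnrichmentResult]",
    annotation=None,
) -> list[GeneScore]:
    """Rank genes by the number of pruned terms supporting them.

    Evidence is query-side: a term supports a gene when the gene is among
    its enrichment hit genes, so the ranking reflects the input sample, not
    the full annotation. Ties break by larger summed -log10(p_emp) over
    supporting terms, then lexicographically. Genes with no supporting term
    are omitted.
    """
    by_term = {r.term_id: r for r in results}
    missing = [t for t in pruned_terms if t not in by_term]
    if missing:
        raise ValueError(f"no enrichment result for pruned terms: {missing}")
    support: dict[str, list[tuple[str, float]]] = {}
    for t in pruned_terms:
        for g in by_term[t].hit_genes:
            support.setdefault(g, []).append((t, by_term[t].p_emp))
    scores = [
        GeneScore(
            gene=g,
            score=len(pairs),
            support=tuple(sorted(pairs)),
            sum_neglog10_p=sum(-math.log10(p) for _, p in pairs),
        )
        for g, pairs in support.items()
    ]
    scores.sort(key=lambda s: (-s.score, -s.sum_neglog10_p, s.gene))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def prioritize(
    results: "list[EnrichmentResult]",
    ontology: OntologyGraph,
    annotation=None,
    params: EnrichmentParams | None = None,
    keep: str = "descendant",
) -> tuple[list[GeneScore], list[str]]:
    """Significant terms -> ancestry antichain -> gene ranking.

    Returns the ranking and the pruned term list for reporting. An empty
    significant set yields an empty ranking, not an error.
    """
    params = params or EnrichmentParams()
    sig = significant(results, params)
    if not sig:
        return [], []
    pruned = prune_redundant_terms([r.term_id for r in sig], ontology, keep=keep)
    return score_genes(pruned, sig, annotation), pruned


def write_ranking_tsv(scores: "list[GeneScore]", path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\tsupporting_terms\tsum_neglog10_p\n")
        for s in scores:
            terms = ",".join(t for t, _ in s.support)
            fh.write(f"{s.rank}\t{s.gene}\t{s.score}\t{terms}\t{s.sum_neglog10_p:.4f}\n")
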