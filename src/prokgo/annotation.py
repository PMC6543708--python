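"""Unified pan-prokaryote gene -> GO annotation schema.

Per-organism (organism, gene, term) records are merged across bacteria and
archaea: gene symbols referring to the same gene in different organisms are
clustered together (case folding plus an optional synonym map), and for each
surviving gene-term pair a relative frequency is computed as the fraction of
organisms carrying the gene whose annotation also carries the pair. Pairs
whose relative frequency falls strictly below the gene-specific median are
excluded; this removes rare associations contributed by a handful of heavily
studied organisms. The retained pairs, optionally propagated to ancestor
terms, form a bidirectional gene <-> term map used as the enrichment
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .ontology import OntologyGraph

RECORD_COLUMNS = ["organism", "gene", "term"]
FREQ_COLUMNS = ["gene", "term", "n_pair", "n_gene", "rel_freq"]


class SynonymCycleError(ValueError):
    """Raised when the alias -> canonical symbol map contains a cycle."""


# ---------------------------------------------------------------------------
# ingest


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (organism, gene, term) TSV; '#' comments allowed."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=RECORD_COLUMNS, dtype=str
    )
    if df.isna().any().any():
        raise ValueError(f"{path}: annotation rows must have 3 non-empty columns")
    return df


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Project a GAF 2.x file onto (organism, gene, term) records.

    Organism comes from the taxon column (13), the gene symbol from the
    DB object symbol column (3) and the term from the GO ID column (5);
    column numbers are 1-based as in the GAF specification.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 13:
                raise ValueError(f"{path}: GAF line has {len(cols)} columns, need >=13")
            taxon = cols[12].split("|")[0]
            rows.append((taxon, cols[2], cols[4]))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS, dtype=str)


def read_synonym_tsv(path: str | Path) -> dict[str, str]:
    """Read a 2-column (alias, canonical) TSV into a symbol map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: synonym map must have exactly 2 columns")
    return dict(zip(df[0].str.casefold(), df[1].str.casefold()))


# ---------------------------------------------------------------------------
# symbol clustering


def _resolve_synonyms(symbol: str, synonym_map: Mapping[str, str]) -> str:
    seen = {symbol}
    while symbol in synonym_map:
        symbol = synonym_map[symbol]
        if symbol in seen:
            raise SynonymCycleError(f"synonym map contains a cycle through {symbol!r}")
        seen.add(symbol)
    return symbol


def cluster_gene_symbols(
    records: pd.DataFrame, synonym_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Case-fold gene symbols, apply synonyms, and de-duplicate triples.

    Symbols from different organisms that name the same gene collapse onto
    one canonical lower-case symbol so their annotations can be combined.
    Output rows are sorted (organism, gene, term) for determinism.
    """
    out = records.copy()
    out["gene"] = out["gene"].str.casefold()
    if synonym_map:
        folded = {a.casefold(): c.casefold() for a, c in synonym_map.items()}
        cache: dict[str, str] = {}
        for sym in out["gene"].unique():
            cache[sym] = _resolve_synonyms(sym, folded)
        out["gene"] = out["gene"].map(cache)
    out = (
        out.drop_duplicates(RECORD_COLUMNS)
        .sort_values(RECORD_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# relative frequencies and the median filter


def compute_pair_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Relative frequency of every (gene, term) pair across organisms.

    ``n_gene`` counts organisms with at least one annotation record for the
    gene (the operational reading of "organisms containing the gene");
    ``n_pair`` counts organisms whose records include the specific pair;
    ``rel_freq = n_pair / n_gene``.
    """
    if records.empty:
        return pd.DataFrame(columns=FREQ_COLUMNS)
    dedup = records.drop_duplicates(RECORD_COLUMNS)
    n_gene = dedup.groupby("gene")["organism"].nunique()
    pair = (
        dedup.groupby(["gene", "term"])["organism"]
        .nunique()
        .rename("n_pair")
        .reset_index()
    )
    pair["n_gene"] = pair["gene"].map(n_gene)
    pair["rel_freq"] = pair["n_pair"] / pair["n_gene"]
    return pair[FREQ_COLUMNS].sort_values(["gene", "term"], kind="mergesort").reset_index(
        drop=True
    )


def median_filter(frequencies: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split pairs into (retained, excluded) by the gene-specific median.

    For each gene the median of its rel_freq distribution is computed
    (midpoint convention for even-length distributions); pairs strictly
    below the median are excluded, pairs at or above it retained. A gene
    with a single pair is always retained (its median equals its value).
    """
    if frequencies.empty:
        empty = frequencies.copy()
        return empty, empty.copy()
    med = frequencies.groupby("gene")["rel_freq"].transform("median")
    excluded_mask = frequencies["rel_freq"] < med
    retained = frequencies[~excluded_mask].reset_index(drop=True)
    excluded = frequencies[excluded_mask].reset_index(drop=True)
    return retained, excluded


# ---------------------------------------------------------------------------
# unified annotation


@dataclass
class UnifiedAnnotation:
    """Frequency-filtered bidirectional gene <-> term map.

    ``gene_to_terms`` and ``term_to_genes`` are exact inverses; every term
    resolves in the ontology and carries a namespace tag. ``n_retained`` /
    ``n_excluded`` record the median-filter outcome on raw pairs and
    ``rejects`` lists term accessions that could not be resolved.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    term_namespace: dict[str, str]
    frequencies: pd.DataFrame  # raw pair table with a retained flag
    n_retained: int
    n_excluded: int
    rejects: list[str] = field(default_factory=list)

    def genes(self) -> list[str]:
        return sorted(self.gene_to_terms)

    def restrict(self, namespace: str) -> dict[str, frozenset[str]]:
        """term -> genes map limited to one GO domain."""
        return {
            t: g
            for t, g in self.term_to_genes.items()
            if self.term_namespace[t] == namespace
        }

    def write_tsv(self, path: str | Path) -> None:
        """Persist the pair table (gene, term, rel_freq, retained flag)."""
        self.frequencies.to_csv(
            path,
            sep="\t",
            index=False,
            columns=["gene", "term", "rel_freq", "retained"],
        )


def build_unified_annotation(
    records: pd.DataFrame,
    ontology: OntologyGraph,
    propagate: bool = True,
    synonym_map: Mapping[str, str] | None = None,
) -> UnifiedAnnotation:
    """Cluster symbols, compute frequencies, median-filter, and index.

    The median filter runs on the raw (unpropagated) pairs; if ``propagate``
    is on, each retained (gene, term) additionally implies (gene, ancestor)
    for every ancestor in the term's namespace, per the GO true-path rule.
    Term accessions are resolved through alt_ids; unresolvable ones go to
    the rejects list rather than aborting the build.
    """
    if records.empty:
        raise ValueError("empty annotation corpus: no records to unify")
    clustered = cluster_gene_symbols(records, synonym_map)

    resolved = clustered["term"].map(lambda t: ontology.resolve(t))
    rejects = sorted(clustered.loc[resolved.isna(), "term"].unique())
    clustered = clustered.assign(term=resolved).dropna(subset=["term"])
    clustered = clustered[clustered["term"].map(lambda t: t in ontology)]
    if clustered.empty:
        raise ValueError("no annotation records with resolvable ontology terms")

    freq = compute_pair_frequencies(clustered)
    retained, excluded = median_filter(freq)
    table = freq.copy()
    excluded_keys = set(zip(excluded["gene"], excluded["term"]))
    table["retained"] = [
        (g, t) not in excluded_keys for g, t in zip(table["gene"], table["term"])
    ]

    gene_to_terms: dict[str, set[str]] = {}
    for gene, term in zip(retained["gene"], retained["term"]):
        terms = gene_to_terms.setdefault(gene, set())
        terms.add(term)
        if propagate:
            ns = ontology.namespace_of(term)
            terms.update(
                a for a in ontology.ancestors(term) if ontology.namespace_of(a) == ns
            )

    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for term in terms:
            term_to_genes.setdefault(term, set()).add(gene)

    return UnifiedAnnotation(
        gene_to_terms={g: frozenset(t) for g, t in gene_to_terms.items()},
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        term_namespace={t: ontology.namespace_of(t) for t in term_to_genes},
        frequencies=table,
        n_retained=len(retained),
        n_excluded=len(excluded),
        rejects=rejects,
    )


def load_unified_tsv(path: str | Path, ontology: OntologyGraph) -> UnifiedAnnotation:
    """Rebuild a :class:`UnifiedAnnotation` from a persisted pair table.

    Ancestor propagation is re-applied from the retained pairs, so a cached
    table produces the same maps as an in-memory build with propagate on.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "term": str})
    expected = {"gene", "term", "rel_freq", "retained"}
    if not expected.issubset(table.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    retained = table[table["retained"]]
    gene_to_terms: dict[str, set[str]] = {}
    for gene, term in zip(retained["gene"], retained["term"]):
        ns = ontology.namespace_of(term)
        terms = gene_to_terms.setdefault(gene, set())
        terms.add(term)
        terms.update(
            a for a in ontology.ancestors(term) if ontology.namespace_of(a) == ns
        )
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for term in terms:
            term_to_genes.setdefault(term, set()).add(gene)
    return UnifiedAnnotation(
        gene_to_terms={g: frozenset(t) for g, t in gene_to_terms.items()},
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        term_namespace={t: ontology.namespace_of(t) for t in term_to_genes},
        frequencies=table,
        n_retained=int(table["retained"].sum()),
        n_excluded=int((~table["retained"]).sum()),
    )
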