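"""Seeded synthetic fixtures with planted ground truth.

Every input the pipeline consumes can be generated here: a small acyclic
ontology across the three GO namespaces, a multi-organism annotation corpus
with controlled gene-term relative frequencies, BLASTp tabular files with
controlled coverage and e-value distributions, and query gene lists with
planted over-represented terms. Each generator records the planted truth
(noise pairs destined for median exclusion, per-row BLAST pass labels,
enriched terms, a hub gene) so downstream stages can be tested end to end
without any external download.

All generators are pure functions of the :class:`FixtureSpec`: the same seed
yields byte-identical artifacts. Sub-seeds for the individual artifacts are
derived from the spec seed by fixed offsets, so each artifact is also
independently reproducible.

The corpus generator plants noise by construction: a gene's core terms are
annotated in every organism carrying the gene (relative frequency 1.0) while
noise pairs appear in a single organism. As long as a gene has no more noise
pairs than core pairs, the gene-specific median stays at or above the
midpoint between the noise frequencies and 1.0, so exactly the noise pairs
fall strictly below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import RECORD_COLUMNS
from .blastfilter import AlignmentHit, FilterParams
from .enrichment import GeneUniverse
from .ontology import NAMESPACES, OntologyGraph, load_obo_text

# fixed sub-seed offsets, one per artifact
_ONTOLOGY_OFFSET = 0
_CORPUS_OFFSET = 1
_BLAST_OFFSET = 2
_QUERY_OFFSET = 3


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_terms_per_namespace: int = 60
    max_parents: int = 3
    min_root_children: int = 0
    n_organisms: int = 20
    n_genes: int = 200
    core_terms_min: int = 1
    core_terms_max: int = 3
    noise_pair_rate: float = 0.1
    planted_terms: tuple[str, ...] = ()
    planted_term_size: int = 40
    effect_size: float = 0.0
    n_query: int = 30
    n_blast_rows: int = 500
    blast_pass_fraction: float = 0.7
    blast_evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        for name in (
            "n_terms_per_namespace",
            "max_parents",
            "n_organisms",
            "n_genes",
            "n_query",
            "n_blast_rows",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_pair_rate", "effect_size", "blast_pass_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_organisms < 2:
            raise ValueError("need at least 2 organisms to plant noise pairs")


@dataclass
class FixtureTruth:
    """Planted ground truth; generators fill the fields they control."""

    noise_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    hub_gene: str | None = None
    blast_labels: list[bool] = field(default_factory=list)


def _rng(spec: FixtureSpec, offset: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed * 7 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(spec: FixtureSpec, path: str | Path | None = None
                      ) -> tuple[str, OntologyGraph]:
    """Rooted random DAG per namespace, acyclic by construction.

    Term i attaches to 1..max_parents earlier terms of its namespace; the
    first ``min_root_children`` terms attach directly to the root, which
    guarantees that many disjoint branches when ``max_parents`` is 1.
    """
    rng = _rng(spec, _ONTOLOGY_OFFSET)
    lines = ["format-version: 1.2", "ontology: synthetic-fixture", ""]
    for d, namespace in enumerate(NAMESPACES, start=1):
        ids = [f"GO:{d}{i:06d}" for i in range(1, spec.n_terms_per_namespace + 1)]
        for i, term in enumerate(ids):
            lines += [
                "[Term]",
                f"id: {term}",
                f"name: synthetic {namespace.replace('_', ' ')} term {i + 1}",
                f"namespace: {namespace}",
            ]
            if i > 0:
                if i <= spec.min_root_children:
                    parents = [ids[0]]
                else:
                    k = min(int(rng.integers(1, spec.max_parents + 1)), i)
                    parents = sorted(
                        ids[j] for j in rng.choice(i, size=k, replace=False)
                    )
                lines += [f"is_a: {p}" for p in parents]
            lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text, load_obo_text(text)


# ---------------------------------------------------------------------------
# annotation corpus


def generate_corpus(
    spec: FixtureSpec,
    graph: OntologyGraph,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, FixtureTruth]:
    """Multi-organism annotation records with planted low-frequency noise.

    Each gene lives in >=2 organisms, carries 1..core_terms_max core terms
    per namespace annotated in every one of them, and (at rate
    ``noise_pair_rate``, capped at the core count) noise pairs annotated in
    a single organism — guaranteed below the gene median. Planted terms are
    additionally core-annotated to exactly ``planted_term_size`` genes, so
    a leaf planted term has exactly that many genes in the universe.
    """
    rng = _rng(spec, _CORPUS_OFFSET)
    genes = [f"g{i:04d}" for i in range(1, spec.n_genes + 1)]
    organisms = [f"org{j:03d}" for j in range(1, spec.n_organisms + 1)]
    planted_set = set(spec.planted_terms)
    by_namespace = {
        ns: sorted(
            t for t in graph.graph
            if graph.terms[t].namespace == ns
            and graph.graph.out_degree(t) > 0
            and t not in planted_set
        )
        for ns in NAMESPACES
    }
    all_terms = sorted(t for terms in by_namespace.values() for t in terms)

    truth = FixtureTruth()
    planted_assign: dict[str, set[str]] = {t: set() for t in spec.planted_terms}
    for term in spec.planted_terms:
        if term not in graph:
            raise ValueError(f"planted term {term} not in ontology")
        chosen = rng.choice(spec.n_genes, size=spec.planted_term_size, replace=False)
        planted_assign[term] = {genes[i] for i in sorted(chosen)}
        truth.planted_genes[term] = frozenset(planted_assign[term])

    rows: list[tuple[str, str, str]] = []
    for gene in genes:
        n_orgs = int(rng.integers(2, spec.n_organisms + 1))
        orgs = sorted(
            organisms[j] for j in rng.choice(spec.n_organisms, n_orgs, replace=False)
        )
        core: set[str] = set()
        for ns in NAMESPACES:
            pool = by_namespace[ns]
            k = min(int(rng.integers(spec.core_terms_min, spec.core_terms_max + 1)),
                    len(pool))
            core.update(pool[j] for j in rng.choice(len(pool), k, replace=False))
        for term, members in planted_assign.items():
            if gene in members:
                core.add(term)
        for org in orgs:
            for term in sorted(core):
                rows.append((org, gene, term))
        # noise: single-organism pairs, never more numerous than core pairs
        n_noise = min(int(rng.binomial(len(core), spec.noise_pair_rate)), len(core))
        noise_pool = [t for t in all_terms if t not in core]
        if n_noise and noise_pool:
            picks = rng.choice(len(noise_pool), min(n_noise, len(noise_pool)),
                               replace=False)
            for j in sorted(picks):
                term = noise_pool[j]
                org = orgs[int(rng.integers(len(orgs)))]
                rows.append((org, gene, term))
                truth.noise_pairs.add((gene, term))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# organism\tgene\tterm\n")
        records.to_csv(path, sep="\t", header=False, index=False, mode="a")
    return records, truth


def generate_id_map(
    spec: FixtureSpec, path: str | Path | None = None
) -> dict[str, str]:
    """One synthetic accession per gene symbol (P00001-style)."""
    id_map = {
        f"P{i:05d}": f"g{i:04d}" for i in range(1, spec.n_genes + 1)
    }
    if path is not None:
        with open(path, "w") as fh:
            for acc in sorted(id_map):
                fh.write(f"{acc}\t{id_map[acc]}\n")
    return id_map


# ---------------------------------------------------------------------------
# BLAST tabular


def _span_at_least(rng: np.random.Generator, length: int, num: int, den: int) -> int:
    """A span with span/length >= num/den, chosen uniformly."""
    lo = -(-num * length // den)  # ceil
    return int(rng.integers(lo, length + 1))


def _span_below(rng: np.random.Generator, length: int, num: int, den: int) -> int:
    """A span with span/length < num/den (at least 1 residue)."""
    hi = -(-num * length // den)  # first passing span
    return int(rng.integers(1, max(hi, 2)))


def generate_blast(
    spec: FixtureSpec,
    id_map: dict[str, str],
    path: str | Path | None = None,
) -> tuple[list[AlignmentHit], FixtureTruth]:
    """BLASTp tabular rows with per-row pass/fail labels.

    A fraction ``blast_pass_fraction`` of rows satisfies all of: query
    coverage >= 90%, subject coverage >= 50%, e-value <= the spec cutoff;
    the rest violate at least one predicate. Every tenth passing row sits
    exactly on a coverage boundary (coverage exactly 0.90 or 0.50). Spans
    are integer-constructed against the rational thresholds, so labels are
    unambiguous.
    """
    rng = _rng(spec, _BLAST_OFFSET)
    accessions = sorted(id_map)
    truth = FixtureTruth()
    hits: list[AlignmentHit] = []
    log_cut = math.log10(spec.blast_evalue_cutoff)
    for i in range(spec.n_blast_rows):
        passing = bool(rng.random() < spec.blast_pass_fraction)
        boundary = passing and i % 10 == 0
        if boundary:
            q_len, s_len = 10 * int(rng.integers(10, 41)), 2 * int(rng.integers(50, 201))
            q_span, s_span = 9 * q_len // 10, s_len // 2
        else:
            q_len = int(rng.integers(80, 401))
            s_len = int(rng.integers(80, 401))
            if passing:
                q_span = _span_at_least(rng, q_len, 9, 10)
                s_span = _span_at_least(rng, s_len, 1, 2)
            else:
                mode = int(rng.integers(3))  # which predicate to break
                q_span = (_span_below(rng, q_len, 9, 10) if mode == 0
                          else _span_at_least(rng, q_len, 9, 10))
                s_span = (_span_below(rng, s_len, 1, 2) if mode == 1
                          else _span_at_least(rng, s_len, 1, 2))
        if passing:
            evalue = 10.0 ** rng.uniform(-50.0, log_cut)
        elif not boundary and mode == 2:
            evalue = 10.0 ** rng.uniform(log_cut + 0.5, 3.0)
        else:
            evalue = 10.0 ** rng.uniform(-50.0, log_cut)
        q_start = int(rng.integers(1, q_len - q_span + 2))
        s_start = int(rng.integers(1, s_len - s_span + 2))
        hits.append(
            AlignmentHit(
                query_id=f"q{i + 1:05d}",
                subject_id=accessions[int(rng.integers(len(accessions)))],
                percent_identity=round(float(rng.uniform(30, 100)), 3),
                alignment_length=q_span,
                mismatches=int(rng.integers(0, q_span // 4 + 1)),
                gap_opens=int(rng.integers(0, 5)),
                q_start=q_start,
                q_end=q_start + q_span - 1,
                s_start=s_start,
                s_end=s_start + s_span - 1,
                evalue=float(evalue),
                bit_score=round(float(rng.uniform(40, 600)), 1),
                q_len=q_len,
                s_len=s_len,
            )
        )
        truth.blast_labels.append(passing)
    if path is not None:
        with open(path, "w") as fh:
            for hit in hits:
                fh.write(hit.to_row() + "\n")
    return hits, truth


def blast_filter_params(spec: FixtureSpec) -> FilterParams:
    """The thresholds under which the planted labels were assigned."""
    return FilterParams(max_evalue=spec.blast_evalue_cutoff)


# ---------------------------------------------------------------------------
# query gene lists


def generate_query(
    spec: FixtureSpec,
    universe: GeneUniverse,
    path: str | Path | None = None,
    hub_gene: str | None = None,
) -> list[str]:
    """Query with an ``effect_size`` fraction drawn from planted-term genes.

    The remainder is drawn uniformly from the rest of the universe; with
    effect_size 0 this is a null query. Raises if a planted term is absent
    from the universe or too small to supply its share.
    """
    rng = _rng(spec, _QUERY_OFFSET)
    n_planted = round(spec.effect_size * spec.n_query)
    pool: set[str] = set()
    for term in spec.planted_terms:
        members = universe.term_genes.get(term)
        if not members or len(members) < 2:
            raise ValueError(
                f"infeasible plant: term {term} missing from universe or too small"
            )
        pool |= members
    if n_planted > len(pool):
        raise ValueError(
            f"infeasible plant: need {n_planted} genes, planted terms supply {len(pool)}"
        )
    query: list[str] = []
    if hub_gene is not None:
        query.append(hub_gene)
    if n_planted:
        ordered = sorted(pool - set(query))
        take = min(n_planted, len(ordered))
        query += [ordered[j] for j in rng.choice(len(ordered), take, replace=False)]
    rest = sorted(set(universe.genes) - set(query))
    n_fill = spec.n_query - len(query)
    if n_fill > 0:
        query += [rest[j] for j in rng.choice(len(rest), n_fill, replace=False)]
    if path is not None:
        with open(path, "w") as fh:
            fh.write("# synthetic query gene list\n")
            for g in query:
                fh.write(g + "\n")
    return query


# ---------------------------------------------------------------------------
# hub fixture for prioritization


@dataclass
class HubFixture:
    graph: OntologyGraph
    records: pd.DataFrame
    query: list[str]
    hub_gene: str
    branch_terms: tuple[str, ...]


def generate_hub_fixture(
    seed: int,
    n_branches: int = 3,
    n_genes: int = 200,
    n_terms_per_namespace: int = 40,
    genes_per_branch_term: int = 8,
    n_background_query: int = 5,
) -> HubFixture:
    """A planted-hub scenario: one gene annotated across disjoint branches.

    The biological-process namespace is generated as a tree whose root has
    at least ``n_branches`` children, so the branches are disjoint subtrees.
    One leaf per branch is chosen; the hub gene is annotated to all of them
    while every other gene's biological-process annotation stays inside a
    single branch. The query contains the hub, ``genes_per_branch_term``
    genes per chosen leaf, and a few uniform background genes, so each
    chosen leaf comes out enriched and the hub supports all of them.
    """
    spec = FixtureSpec(
        seed=seed,
        n_terms_per_namespace=n_terms_per_namespace,
        max_parents=1,
        min_root_children=n_branches,
        n_genes=n_genes,
        noise_pair_rate=0.0,
    )
    _, graph = generate_ontology(spec)
    rng = _rng(spec, _CORPUS_OFFSET)

    bp_root = sorted(graph.roots("biological_process"))[0]
    branch_heads = sorted(graph.graph.predecessors(bp_root))
    assert len(branch_heads) >= n_branches
    branch_of: dict[str, str] = {}
    for head in branch_heads:
        branch_of[head] = head
        for t in graph.descendants(head):
            branch_of[t] = head
    chosen_heads = branch_heads[:n_branches]
    leaves = []
    for head in chosen_heads:
        members = sorted({head} | graph.descendants(head))
        candidates = [t for t in members if graph.graph.in_degree(t) == 0]
        leaves.append(candidates[int(rng.integers(len(candidates)))])

    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    hub = genes[0]
    organisms = [f"org{j:03d}" for j in range(1, spec.n_organisms + 1)]
    other_ns_terms = sorted(
        t for t in graph.graph
        if graph.terms[t].namespace != "biological_process"
        and graph.graph.out_degree(t) > 0
    )
    bp_by_branch = {
        head: sorted({head} | graph.descendants(head)) for head in branch_heads
    }

    rows: list[tuple[str, str, str]] = []
    leaf_members: dict[str, list[str]] = {leaf: [] for leaf in leaves}
    gene_branch: dict[str, str] = {}
    gene_orgs: dict[str, list[str]] = {}
    for gene in genes:
        n_orgs = int(rng.integers(2, spec.n_organisms + 1))
        orgs = sorted(
            organisms[j] for j in rng.choice(spec.n_organisms, n_orgs, replace=False)
        )
        gene_orgs[gene] = orgs
        if gene == hub:
            core = set(leaves)
        else:
            head = branch_heads[int(rng.integers(len(branch_heads)))]
            gene_branch[gene] = head
            # chosen leaves are reserved for the planted members added below,
            # so their universe size stays controlled
            pool = [t for t in bp_by_branch[head] if t not in leaves]
            k = min(int(rng.integers(1, 3)), len(pool))
            core = {pool[j] for j in rng.choice(len(pool), k, replace=False)}
        core.update(
            other_ns_terms[j]
            for j in rng.choice(len(other_ns_terms), 2, replace=False)
        )
        for org in orgs:
            for term in sorted(core):
                rows.append((org, gene, term))

    # top up each chosen leaf from its own branch so it has enough
    # query-eligible members; non-hub genes stay confined to one branch
    extra_rows: list[tuple[str, str, str]] = []
    for leaf in leaves:
        head = branch_of[leaf]
        need = genes_per_branch_term + 2 - len(leaf_members[leaf])
        candidates = [
            g for g in genes[1:]
            if gene_branch.get(g) == head and g not in leaf_members[leaf]
        ]
        for j in rng.choice(len(candidates), min(max(need, 0), len(candidates)),
                            replace=False):
            gene = candidates[int(j)]
            leaf_members[leaf].append(gene)
            for org in gene_orgs[gene]:
                extra_rows.append((org, gene, leaf))
    rows += extra_rows

    query = [hub]
    for leaf in leaves:
        members = [g for g in sorted(set(leaf_members[leaf])) if g not in query]
        take = min(genes_per_branch_term, len(members))
        query += [members[j] for j in rng.choice(len(members), take, replace=False)]
    rest = sorted(set(genes) - set(query))
    query += [rest[j] for j in rng.choice(len(rest), n_background_query, replace=False)]

    records = pd.DataFrame(sorted(set(rows)), columns=RECORD_COLUMNS)
    return HubFixture(
        graph=graph,
        records=records,
        query=query,
        hub_gene=hub,
        branch_terms=tuple(leaves),
    )


# ---------------------------------------------------------------------------
# truth manifest


def write_truth(truth: FixtureTruth, path: str | Path) -> None:
    """Key-value text manifest: one fact per line, tab-separated."""
    with open(path, "w") as fh:
        for gene, term in sorted(truth.noise_pairs):
            fh.write(f"noise_pair\t{gene}\t{term}\n")
        for term in sorted(truth.planted_genes):
            fh.write(f"planted_term\t{term}\t{','.join(sorted(truth.planted_genes[term]))}\n")
        if truth.hub_gene:
            fh.write(f"hub_gene\t{truth.hub_gene}\n")
        for i, label in enumerate(truth.blast_labels):
            fh.write(f"blast_label\t{i}\t{int(label)}\n")
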