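"""Over-representation analysis with permutation and FDR correction.

A query gene list is tested against the unified annotation restricted to a
single GO domain. Each informative term receives a one-sided hypergeometric
tail p-value (over-representation side), an empirical p-value from resampled
null queries (a non-parametric correction that absorbs annotation noise),
and a Benjamini-Hochberg adjusted q-value. Trivial terms (too few annotated
genes to be testable) and non-informative ones (covering a large share of
the background) are filtered out before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import UnifiedAnnotation
from .ontology import _check_namespace


class EmptyQueryError(ValueError):
    """No query gene is annotated in the background universe."""


@dataclass
class GeneUniverse:
    """Enrichment background: annotated genes plus per-term gene sets of one
    GO domain. Terms with no annotated gene are absent by construction."""

    genes: tuple[str, ...]
    term_genes: dict[str, frozenset[str]]
    namespace: str

    def __post_init__(self) -> None:
        universe = set(self.genes)
        for term, members in self.term_genes.items():
            if not members <= universe:
                raise ValueError(f"term {term} has genes outside the universe")

    @classmethod
    def from_unified(cls, annotation: UnifiedAnnotation, namespace: str) -> "GeneUniverse":
        _check_namespace(namespace)
        term_genes = annotation.restrict(namespace)
        genes = sorted(set().union(*term_genes.values())) if term_genes else []
        return cls(genes=tuple(genes), term_genes=term_genes, namespace=namespace)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentParams:
    namespace: str = "biological_process"
    min_term_genes: int = 2
    max_term_fraction: float = 0.25
    alpha: float = 0.05
    n_resamples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        _check_namespace(self.namespace)
        if not (0 < self.max_term_fraction <= 1):
            raise ValueError("max_term_fraction must be in (0, 1]")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be at least 100")


@dataclass
class EnrichmentResult:
    """Per-term outcome: overlap k of the query with a term of size K, in a
    query of size n over a universe of size N, with raw, empirical and
    BH-adjusted p-values."""

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_emp: float
    q_bh: float
    hit_genes: tuple[str, ...]


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The upper tail of drawing ``n`` genes without replacement from a
    universe of ``N`` of which ``K`` carry the term, observing ``k`` or
    more carriers. Delegates to the survival function of
    :class:`scipy.stats.hypergeom`, which sums the tail in a numerically
    stable way.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def informativeness_filter(
    term_sizes: dict[str, int], universe_size: int, params: EnrichmentParams
) -> set[str]:
    """Terms with min_term_genes <= size <= max_term_fraction * universe.

    Singleton terms cannot be over-represented meaningfully and root-like
    terms annotating a large share of the universe carry no information.
    """
    upper = params.max_term_fraction * universe_size
    return {
        t
        for t, size in term_sizes.items()
        if params.min_term_genes <= size <= upper
    }


def permutation_correction(
    k_obs: dict[str, int],
    universe: GeneUniverse,
    n_query: int,
    params: EnrichmentParams,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Empirical p-values from uniformly resampled null queries.

    For each of ``n_resamples`` draws of ``n_query`` genes without
    replacement from the universe, per-term overlap counts are recomputed;
    ``p_emp(term) = (1 + #{draws with k >= k_obs}) / (1 + n_resamples)``
    (add-one smoothing so an empirical p is never zero). Deterministic
    given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    terms = list(k_obs)
    if not terms:
        return {}
    N = universe.size
    gene_index = {g: i for i, g in enumerate(universe.genes)}
    member = np.zeros((len(terms), N), dtype=np.float32)
    for ti, term in enumerate(terms):
        for g in universe.term_genes[term]:
            member[ti, gene_index[g]] = 1.0
    obs = np.array([k_obs[t] for t in terms], dtype=np.int64)

    exceed = np.zeros(len(terms), dtype=np.int64)
    R = params.n_resamples
    chunk = max(1, min(R, 20_000_000 // max(N, 1)))
    done = 0
    while done < R:
        r = min(chunk, R - done)
        # r null queries at once: the n_query smallest random keys per row
        keys = rng.random((r, N))
        idx = np.argpartition(keys, n_query - 1, axis=1)[:, :n_query]
        draws = np.zeros((r, N), dtype=np.float32)
        np.put_along_axis(draws, idx, 1.0, axis=1)
        counts = member @ draws.T  # terms x r overlap counts
        exceed += (counts >= obs[:, None]).sum(axis=1)
        done += r
    p_emp = (1.0 + exceed) / (1.0 + R)
    return {t: float(p) for t, p in zip(terms, p_emp)}


def bh_adjust(p_values: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def enrich(
    query: "list[str]",
    universe: GeneUniverse,
    params: EnrichmentParams,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Full over-representation analysis of a gene list.

    Returns (results, dropped): one result per informative term overlapping
    the query (k >= 1), sorted ascending by (p_emp, p_raw, term_id), plus
    the query genes absent from the universe (dropped with a warning at the
    caller's discretion, not an error). The q-values adjust the empirical
    p-values across all tested terms.
    """
    universe_set = set(universe.genes)
    in_universe = [g for g in dict.fromkeys(query) if g in universe_set]
    dropped = [g for g in dict.fromkeys(query) if g not in universe_set]
    if not in_universe:
        raise EmptyQueryError(
            "no annotated query genes: the query does not intersect the universe"
        )
    n = len(in_universe)
    N = universe.size
    term_sizes = {t: len(g) for t, g in universe.term_genes.items()}
    informative = informativeness_filter(term_sizes, N, params)

    query_set = set(in_universe)
    k_obs = {
        t: len(universe.term_genes[t] & query_set)
        for t in informative
        if universe.term_genes[t] & query_set
    }
    if not k_obs:
        return [], dropped
    p_emp = permutation_correction(k_obs, universe, n, params)

    terms = sorted(k_obs)
    p_raw = {t: hypergeometric_tail(N, term_sizes[t], n, k_obs[t]) for t in terms}
    q = bh_adjust([p_emp[t] for t in terms])
    q_bh = dict(zip(terms, q))

    results = [
        EnrichmentResult(
            term_id=t,
            k=k_obs[t],
            K=term_sizes[t],
            n=n,
            N=N,
            p_raw=p_raw[t],
            p_emp=p_emp[t],
            q_bh=float(q_bh[t]),
            hit_genes=tuple(sorted(universe.term_genes[t] & query_set)),
        )
        for t in terms
    ]
    results.sort(key=lambda r: (r.p_emp, r.p_raw, r.term_id))
    return results, dropped


def significant(results: "list[EnrichmentResult]", params: EnrichmentParams,
                on: str = "q_bh") -> list[EnrichmentResult]:
    """Results called significant at ``alpha``, on q_bh (default) or p_emp."""
    if on not in ("q_bh", "p_emp"):
        raise ValueError("significance criterion must be 'q_bh' or 'p_emp'")
    return [r for r in results if getattr(r, on) <= params.alpha]


def write_enrichment_tsv(
    results: "list[EnrichmentResult]", path, ontology=None
) -> None:
    """TSV export with term metadata when an ontology is supplied."""
    with open(path, "w") as fh:
        fh.write(
            "term_id\tname\tnamespace\tk\tK\tn\tN\tp_raw\tp_emp\tq_bh\thit_genes\n"
        )
        for r in results:
            name = ns = ""
            if ontology is not None and r.term_id in ontology.terms:
                term = ontology.terms[r.term_id]
                name, ns = term.name, term.namespace
            fh.write(
                f"{r.term_id}\t{name}\t{ns}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_raw:.6g}\t{r.p_emp:.6g}\t{r.q_bh:.6g}\t"
                f"{','.join(r.hit_genes)}\n"
            )
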