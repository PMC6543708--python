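"""Annotation unification: symbol clustering, relative frequencies, the
gene-median exclusion filter and the bidirectional unified map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prokgo.annotation import (
    RECORD_COLUMNS,
    SynonymCycleError,
    build_unified_annotation,
    cluster_gene_symbols,
    compute_pair_frequencies,
    load_unified_tsv,
    median_filter,
    read_annotation_tsv,
    read_gaf,
)


def records(*triples):
    return pd.DataFrame(list(triples), columns=RECORD_COLUMNS)


# -- symbol clustering -------------------------------------------------------


def test_case_fold_merges_duplicates():
    out = cluster_gene_symbols(records(("o1", "recA", "t1"), ("o1", "RecA", "t1")))
    assert len(out) == 1
    assert out.iloc[0]["gene"] == "reca"


def test_empty_input_passes_through():
    out = cluster_gene_symbols(records())
    assert out.empty


def test_synonym_map_merges_aliases():
    out = cluster_gene_symbols(
        records(("o2", "recA1", "t1"), ("o1", "recA", "t1")),
        synonym_map={"recA1": "recA"},
    )
    assert set(out["gene"]) == {"reca"}
    assert len(out) == 2  # two organisms, same gene/term


def test_synonym_chain_resolves_transitively():
    out = cluster_gene_symbols(
        records(("o1", "a", "t1")), synonym_map={"a": "b", "b": "c"}
    )
    assert out.iloc[0]["gene"] == "c"


def test_synonym_cycle_rejected():
    with pytest.raises(SynonymCycleError):
        cluster_gene_symbols(records(("o1", "a", "t1")), synonym_map={"a": "b", "b": "a"})


# -- pair frequencies --------------------------------------------------------


def test_forced_ratio():
    rows = [("o%d" % i, "g", "t") for i in (1, 2, 3)]
    rows += [("o%d" % i, "g", "u") for i in (1, 2, 3, 4, 5)]
    freq = compute_pair_frequencies(records(*rows))
    gt = freq.set_index("term").loc["t"]
    assert gt["n_pair"] == 3 and gt["n_gene"] == 5
    assert gt["rel_freq"] == pytest.approx(0.6)


def test_single_organism_gene_has_unit_frequency():
    freq = compute_pair_frequencies(records(("o1", "g", "t")))
    assert freq.iloc[0]["rel_freq"] == 1.0


def test_frequencies_match_set_scan_oracle():
    """Random corpus vs a brute-force per-organism set scan."""
    rng = np.random.default_rng(11)
    rows = {
        (f"o{rng.integers(20)}", f"g{rng.integers(50)}", f"t{rng.integers(30)}")
        for _ in range(2000)
    }
    df = records(*sorted(rows))
    freq = compute_pair_frequencies(df)
    by_org = {}
    for org, gene, term in rows:
        by_org.setdefault(org, set()).add((gene, term))
    for _, row in freq.iterrows():
        n_gene = sum(any(g == row["gene"] for g, _ in pairs) for pairs in by_org.values())
        n_pair = sum((row["gene"], row["term"]) in pairs for pairs in by_org.values())
        assert row["n_pair"] == n_pair and row["n_gene"] == n_gene
        assert row["rel_freq"] == n_pair / n_gene


def test_adding_organism_without_pair_decreases_frequency():
    base = records(("o1", "g", "t"), ("o2", "g", "t"))
    more = records(("o1", "g", "t"), ("o2", "g", "t"), ("o3", "g", "u"))
    f0 = compute_pair_frequencies(base).set_index("term").loc["t", "rel_freq"]
    f1 = compute_pair_frequencies(more).set_index("term").loc["t", "rel_freq"]
    assert f1 < f0


# -- median filter -----------------------------------------------------------


def freq_frame(gene_to_freqs):
    rows = []
    for gene, freqs in gene_to_freqs.items():
        for i, f in enumerate(freqs):
            rows.append({"gene": gene, "term": f"t{i}", "n_pair": 1, "n_gene": 1,
                         "rel_freq": f})
    return pd.DataFrame(rows)


def test_median_filter_strictly_below_median_excluded():
    retained, excluded = median_filter(freq_frame({"g": [1.0, 0.6, 0.2]}))
    assert sorted(retained["rel_freq"]) == [0.6, 1.0]
    assert list(excluded["rel_freq"]) == [0.2]


def test_single_pair_gene_retained():
    retained, excluded = median_filter(freq_frame({"g": [0.3]}))
    assert len(retained) == 1 and excluded.empty


def test_all_equal_frequencies_all_retained():
    retained, excluded = median_filter(freq_frame({"g": [0.5, 0.5, 0.5, 0.5]}))
    assert len(retained) == 4 and excluded.empty


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from(["g1", "g2", "g3"]),
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
        min_size=1,
    )
)
def test_median_filter_conservation(gene_to_freqs):
    """retained + excluded partition the input for any frequency table."""
    frame = freq_frame(gene_to_freqs)
    retained, excluded = median_filter(frame)
    assert len(retained) + len(excluded) == len(frame)
    keys = lambda df: sorted(zip(df["gene"], df["term"]))
    assert sorted(keys(retained) + keys(excluded)) == keys(frame)


# -- unified annotation ------------------------------------------------------


def test_passthrough_when_everything_survives(chain_graph):
    df = records(("o1", "g1", "GO:0000001"), ("o2", "g1", "GO:0000001"))
    unified = build_unified_annotation(df, chain_graph, propagate=False)
    assert unified.gene_to_terms == {"g1": frozenset({"GO:0000001"})}
    assert unified.n_excluded == 0


def test_chain_propagation(chain_graph):
    df = records(("o1", "g1", "GO:0000001"))
    unified = build_unified_annotation(df, chain_graph, propagate=True)
    assert unified.gene_to_terms["g1"] == frozenset(
        {"GO:0000001", "GO:0000002", "GO:0000003"}
    )


def test_alt_id_resolved_and_unknown_rejected(chain_graph):
    df = records(("o1", "g1", "GO:0000099"), ("o1", "g2", "GO:1234567"))
    unified = build_unified_annotation(df, chain_graph, propagate=False)
    assert unified.gene_to_terms["g1"] == frozenset({"GO:0000001"})
    assert unified.rejects == ["GO:1234567"]


def test_planted_noise_pairs_exactly_excluded(fixture_corpus, fixture_graph):
    """The generator's planted low-frequency pairs are exactly the
    median-excluded set."""
    corpus, truth = fixture_corpus
    freq = compute_pair_frequencies(cluster_gene_symbols(corpus))
    _, excluded = median_filter(freq)
    assert set(zip(excluded["gene"], excluded["term"])) == truth.noise_pairs


def test_inverse_maps_consistent(fixture_corpus, fixture_graph):
    corpus, _ = fixture_corpus
    unified = build_unified_annotation(corpus, fixture_graph)
    for gene, terms in unified.gene_to_terms.items():
        for term in terms:
            assert gene in unified.term_to_genes[term]
    for term, genes in unified.term_to_genes.items():
        for gene in genes:
            assert term in unified.gene_to_terms[gene]


def test_propagation_idempotent(fixture_corpus, fixture_graph):
    """Term sets are ancestor-closed: propagating again changes nothing."""
    corpus, _ = fixture_corpus
    unified = build_unified_annotation(corpus, fixture_graph)
    for gene, terms in unified.gene_to_terms.items():
        closed = set(terms)
        for t in terms:
            ns = fixture_graph.namespace_of(t)
            closed |= {
                a for a in fixture_graph.ancestors(t)
                if fixture_graph.namespace_of(a) == ns
            }
        assert closed == set(terms)


def test_empty_corpus_rejected(chain_graph):
    with pytest.raises(ValueError, match="empty"):
        build_unified_annotation(records(), chain_graph)


def test_tsv_roundtrip_reproduces_maps(tmp_path, fixture_corpus, fixture_graph):
    corpus, _ = fixture_corpus
    unified = build_unified_annotation(corpus, fixture_graph)
    path = tmp_path / "unified.tsv"
    unified.write_tsv(path)
    reloaded = load_unified_tsv(path, fixture_graph)
    assert reloaded.gene_to_terms == unified.gene_to_terms
    assert reloaded.term_to_genes == unified.term_to_genes


def test_read_annotation_tsv_and_gaf(tmp_path):
    tsv = tmp_path / "corpus.tsv"
    tsv.write_text("# comment\no1\tgene\tGO:0000001\n")
    df = read_annotation_tsv(tsv)
    assert df.iloc[0].tolist() == ["o1", "gene", "GO:0000001"]

    gaf = tmp_path / "anno.gaf"
    cols = [""] * 17
    cols[0], cols[2], cols[4], cols[12] = "UniProtKB", "recA", "GO:0000001", "taxon:83333"
    gaf.write_text("!gaf-version: 2.2\n" + "\t".join(cols) + "\n")
    df = read_gaf(gaf)
    assert df.iloc[0].tolist() == ["taxon:83333", "recA", "GO:0000001"]
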