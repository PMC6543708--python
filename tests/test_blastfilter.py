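"""BLAST tabular parsing, coverage/e-value filtering and best-hit selection."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prokgo.blastfilter import (
    AlignmentHit,
    BlastParseError,
    FilterParams,
    best_hit_per_query,
    coverage,
    filter_hits,
    map_to_gene_symbols,
    parse_blast_tabular,
    read_id_map,
)
from prokgo.synth import FixtureSpec, blast_filter_params, generate_blast, generate_id_map


def make_hit(**kw):
    base = dict(
        query_id="q1", subject_id="s1", percent_identity=90.0,
        alignment_length=95, mismatches=3, gap_opens=0,
        q_start=1, q_end=95, s_start=1, s_end=95,
        evalue=1e-30, bit_score=200.0, q_len=100, s_len=100,
    )
    base.update(kw)
    return AlignmentHit(**base)


@st.composite
def hits(draw):
    q_len = draw(st.integers(1, 500))
    s_len = draw(st.integers(1, 500))
    q_start = draw(st.integers(1, q_len))
    q_end = draw(st.integers(q_start, q_len))
    s_start = draw(st.integers(1, s_len))
    s_end = draw(st.integers(s_start, s_len))
    return make_hit(
        q_start=q_start, q_end=q_end, q_len=q_len,
        s_start=s_start, s_end=s_end, s_len=s_len,
        alignment_length=q_end - q_start + 1,
        evalue=draw(st.floats(0, 10)),
        bit_score=draw(st.floats(10, 1000)),
    )


# -- parsing -----------------------------------------------------------------


def test_empty_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    assert parse_blast_tabular(path) == []


def test_single_row_fields_mapped_positionally(tmp_path):
    path = tmp_path / "one.tsv"
    path.write_text("q1\ts1\t97.5\t90\t2\t0\t5\t94\t1\t90\t1e-40\t180.3\t100\t120\n")
    [hit] = parse_blast_tabular(path)
    assert hit.query_id == "q1" and hit.subject_id == "s1"
    assert hit.percent_identity == 97.5 and hit.alignment_length == 90
    assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (5, 94, 1, 90)
    assert hit.evalue == 1e-40 and hit.bit_score == 180.3
    assert (hit.q_len, hit.s_len) == (100, 120)


def test_wrong_column_count_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("q1\ts1\t90\n")
    with pytest.raises(BlastParseError, match=":1:"):
        parse_blast_tabular(path)


def test_twelve_column_file_suggests_outfmt(tmp_path):
    path = tmp_path / "plain6.tsv"
    path.write_text("\t".join(["q1", "s1"] + ["1"] * 10) + "\n")
    with pytest.raises(BlastParseError, match="qlen slen"):
        parse_blast_tabular(path)


def test_non_numeric_field_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("q1\ts1\txx\t90\t2\t0\t5\t94\t1\t90\t1e-40\t180\t100\t120\n")
    with pytest.raises(BlastParseError, match=":1:"):
        parse_blast_tabular(path)


def test_generated_file_roundtrips_bit_exactly(tmp_path):
    spec = FixtureSpec(seed=5, n_blast_rows=100)
    id_map = generate_id_map(spec)
    hits_out, _ = generate_blast(spec, id_map, tmp_path / "hits.tsv")
    assert parse_blast_tabular(tmp_path / "hits.tsv") == hits_out


# -- coverage ----------------------------------------------------------------


def test_full_length_hit_has_unit_coverage():
    q_cov, s_cov = coverage(make_hit(q_start=1, q_end=100, q_len=100))
    assert q_cov == 1.0


def test_coverage_forced_arithmetic():
    q_cov, _ = coverage(make_hit(q_start=6, q_end=94, q_len=100, alignment_length=89))
    assert q_cov == pytest.approx(0.89)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(hits())
def test_coverage_always_in_unit_interval(hit):
    q_cov, s_cov = coverage(hit)
    assert 0 < q_cov <= 1 and 0 < s_cov <= 1


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        make_hit(q_start=50, q_end=40)
    with pytest.raises(ValueError):
        make_hit(s_end=200, s_len=100)


# -- filtering ---------------------------------------------------------------


def test_query_coverage_below_ninety_percent_excluded():
    params = FilterParams(max_evalue=1e-5)
    hit = make_hit(q_start=6, q_end=94)  # q_cov 0.89
    assert filter_hits([hit], params) == []


def test_exact_boundary_coverage_retained():
    """Coverage exactly 0.90 / 0.50 passes: only strictly lower is excluded."""
    params = FilterParams(max_evalue=1e-5)
    hit = make_hit(q_start=1, q_end=90, s_start=1, s_end=50, s_len=100,
                   alignment_length=90)
    assert filter_hits([hit], params) == [hit]


def test_evalue_above_threshold_excluded():
    params = FilterParams(max_evalue=1e-5)
    assert filter_hits([make_hit(evalue=1e-3)], params) == []
    assert filter_hits([make_hit(evalue=1e-5)], params) != []


def test_planted_labels_match_filter_decisions():
    spec = FixtureSpec(seed=3, n_blast_rows=500)
    hits_out, truth = generate_blast(spec, generate_id_map(spec))
    params = blast_filter_params(spec)
    decisions = [h in set(filter_hits([h], params)) for h in hits_out]
    assert decisions == truth.blast_labels


def test_filter_output_subset_and_order_preserved():
    spec = FixtureSpec(seed=9, n_blast_rows=200)
    hits_out, _ = generate_blast(spec, generate_id_map(spec))
    kept = filter_hits(hits_out, blast_filter_params(spec))
    positions = [hits_out.index(h) for h in kept]
    assert positions == sorted(positions)  # order-preserving subsequence


# -- best hit ----------------------------------------------------------------


def test_single_hit_is_best():
    hit = make_hit()
    assert best_hit_per_query([hit]) == [hit]


def test_lowest_evalue_wins():
    h1 = make_hit(evalue=1e-10, subject_id="s1")
    h2 = make_hit(evalue=1e-50, subject_id="s2")
    assert best_hit_per_query([h1, h2]) == [h2]


def test_best_hit_matches_sort_oracle():
    rng = random.Random(4)
    pool = []
    for qi in range(50):
        for _ in range(rng.randint(1, 5)):
            pool.append(make_hit(
                query_id=f"q{qi:02d}",
                subject_id=f"s{rng.randint(0, 9)}",
                evalue=rng.choice([1e-50, 1e-20, 1e-10, 1e-10]),
                bit_score=float(rng.randint(50, 300)),
            ))
    oracle = {}
    for q in {h.query_id for h in pool}:
        oracle[q] = sorted(
            (h for h in pool if h.query_id == q),
            key=lambda h: (h.evalue, -h.bit_score, h.subject_id),
        )[0]
    assert best_hit_per_query(pool) == [oracle[q] for q in sorted(oracle)]


def test_best_hit_queries_unique_and_complete():
    spec = FixtureSpec(seed=2, n_blast_rows=300)
    hits_out, _ = generate_blast(spec, generate_id_map(spec))
    best = best_hit_per_query(hits_out)
    assert len({h.query_id for h in best}) == len(best)
    assert {h.query_id for h in best} == {h.query_id for h in hits_out}


def test_filter_then_best_hit_shuffle_invariant():
    spec = FixtureSpec(seed=6, n_blast_rows=300)
    hits_out, _ = generate_blast(spec, generate_id_map(spec))
    params = blast_filter_params(spec)
    ref = best_hit_per_query(filter_hits(hits_out, params))
    shuffled = hits_out[:]
    random.Random(0).shuffle(shuffled)
    assert best_hit_per_query(filter_hits(shuffled, params)) == ref


# -- symbol mapping ----------------------------------------------------------


def test_shared_symbol_deduplicated():
    hits_in = [make_hit(subject_id="s1"), make_hit(query_id="q2", subject_id="s2")]
    genes, unmapped = map_to_gene_symbols(hits_in, {"s1": "recA", "s2": "recA"})
    assert genes == ["recA"] and unmapped == []


def test_empty_id_map_reports_all_unmapped():
    genes, unmapped = map_to_gene_symbols([make_hit()], {})
    assert genes == [] and unmapped == ["s1"]


def test_full_id_map_leaves_nothing_unmapped(tmp_path):
    spec = FixtureSpec(seed=8, n_blast_rows=100)
    id_map = generate_id_map(spec, tmp_path / "idmap.tsv")
    assert read_id_map(tmp_path / "idmap.tsv") == id_map
    hits_out, _ = generate_blast(spec, id_map)
    genes, unmapped = map_to_gene_symbols(hits_out, id_map)
    assert unmapped == []
    assert len(genes) <= len(hits_out)
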