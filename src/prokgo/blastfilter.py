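"""BLASTp tabular hit parsing, coverage/e-value filtering and best-hit choice.

Input is the 14-column tabular dialect
``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore qlen slen`` (the 12 standard outfmt-6 columns plus query and
subject lengths, which are required to compute coverage). Hits with query
coverage below 90% or subject coverage below 50% are discarded, together
with hits above a user-chosen e-value ceiling; one best hit per query is
kept and subject accessions are translated to gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

N_COLUMNS = 14
OUTFMT = (
    "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore qlen slen"
)


class BlastParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One BLASTp tabular row; coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValueError(
                f"invalid query coordinates {self.q_start}-{self.q_end} (len {self.q_len})"
            )
        if not (1 <= self.s_start <= self.s_end <= self.s_len):
            raise ValueError(
                f"invalid subject coordinates {self.s_start}-{self.s_end} (len {self.s_len})"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    def to_row(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.query_id,
                self.subject_id,
                self.percent_identity,
                self.alignment_length,
                self.mismatches,
                self.gap_opens,
                self.q_start,
                self.q_end,
                self.s_start,
                self.s_end,
                self.evalue,
                self.bit_score,
                self.q_len,
                self.s_len,
            )
        )


@dataclass(frozen=True)
class FilterParams:
    """Alignment stringency thresholds; the e-value ceiling has no default
    because it is a per-analysis choice."""

    max_evalue: float
    min_query_cov: float = 0.90
    min_subject_cov: float = 0.50

    def __post_init__(self) -> None:
        for name, frac in (
            ("min_query_cov", self.min_query_cov),
            ("min_subject_cov", self.min_subject_cov),
        ):
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {frac}")
        if self.max_evalue <= 0:
            raise ValueError(f"max_evalue must be positive, got {self.max_evalue}")


def parse_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 14-column BLAST tabular file, preserving row order.

    Blank lines and '#' comment lines are skipped. A 12-column file (plain
    outfmt 6 without lengths) is rejected with a hint naming the required
    -outfmt string, because coverage cannot be computed without lengths.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != N_COLUMNS:
                hint = ""
                if len(cols) == 12:
                    hint = (
                        "; file looks like plain outfmt 6 without lengths — "
                        f"re-run BLAST with -outfmt '{OUTFMT}'"
                    )
                raise BlastParseError(
                    f"{path}:{lineno}: expected {N_COLUMNS} tab-separated columns, "
                    f"got {len(cols)}{hint}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bit_score=float(cols[11]),
                        q_len=int(cols[12]),
                        s_len=int(cols[13]),
                    )
                )
            except ValueError as exc:
                raise BlastParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(hit.to_row() + "\n")


def coverage(hit: AlignmentHit) -> tuple[float, float]:
    """(query, subject) coverage as the aligned-span fraction of full length.

    Computed from coordinates, not ``alignment_length``, which counts gap
    columns and can exceed the spanned residues.
    """
    q_cov = (hit.q_end - hit.q_start + 1) / hit.q_len
    s_cov = (hit.s_end - hit.s_start + 1) / hit.s_len
    return q_cov, s_cov


def passes_filter(hit: AlignmentHit, params: FilterParams) -> bool:
    q_cov, s_cov = coverage(hit)
    return (
        q_cov >= params.min_query_cov
        and s_cov >= params.min_subject_cov
        and hit.evalue <= params.max_evalue
    )


def filter_hits(hits: Sequence[AlignmentHit], params: FilterParams) -> list[AlignmentHit]:
    """Keep hits meeting all three thresholds, preserving input order.

    Boundary semantics follow the stated cutoffs: coverage *lower than* the
    threshold is excluded, so a hit at exactly 90%/50% coverage is retained.
    """
    return [h for h in hits if passes_filter(h, params)]


def best_hit_per_query(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """One hit per query: lowest e-value, then highest bit score, then the
    lexicographically smallest subject accession. Output sorted by query."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        key = (hit.evalue, -hit.bit_score, hit.subject_id)
        cur = best.get(hit.query_id)
        if cur is None or key < (cur.evalue, -cur.bit_score, cur.subject_id):
            best[hit.query_id] = hit
    return [best[q] for q in sorted(best)]


def read_id_map(path: str | Path) -> dict[str, str]:
    """Load a 2-column (accession, gene symbol) TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            out[cols[0]] = cols[1]
    return out


def map_to_gene_symbols(
    hits: Sequence[AlignmentHit], id_map: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Translate subject accessions to gene symbols.

    Returns unique symbols in first-seen order plus the list of accessions
    with no mapping (reported, not fatal).
    """
    genes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for hit in hits:
        symbol = id_map.get(hit.subject_id)
        if symbol is None:
            unmapped.append(hit.subject_id)
            continue
        if symbol not in seen:
            seen.add(symbol)
            genes.append(symbol)
    return genes, unmapped


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments, de-duplicated
    preserving first-seen order."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line and line not in seen:
                seen.add(line)
                genes.append(line)
    return genes
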