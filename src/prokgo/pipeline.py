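"""End-to-end orchestration: BLAST hits or gene list -> enriched terms ->
ranked candidate master regulators.

The pipeline mirrors the two entry branches of the workflow: a BLASTp
tabular file is parsed, coverage/e-value filtered, reduced to one best hit
per query and translated to gene symbols, or a pre-defined gene list is
read directly. Either way the genes are tested for GO term
over-representation in the user-chosen namespace against the unified
pan-prokaryote annotation, and the significant terms feed the
master-regulator ranking. Every stage writes its artifact plus a flat
key-value run report sufficient to re-run the pipeline identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import (
    UnifiedAnnotation,
    build_unified_annotation,
    load_unified_tsv,
    read_annotation_tsv,
)
from .blastfilter import (
    FilterParams,
    best_hit_per_query,
    filter_hits,
    map_to_gene_symbols,
    parse_blast_tabular,
    read_gene_list,
    read_id_map,
    write_blast_tabular,
    write_gene_list,
)
from .enrichment import (
    EnrichmentParams,
    GeneUniverse,
    enrich,
    significant,
    write_enrichment_tsv,
)
from .ontology import load_obo
from .prioritize import prioritize, write_ranking_tsv


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_path: str
    input_kind: str  # "blast" or "genelist"
    obo_path: str
    outdir: str
    corpus_path: str | None = None
    unified_path: str | None = None
    id_map_path: str | None = None
    filter_params: FilterParams | None = None
    enrichment_params: EnrichmentParams = field(default_factory=EnrichmentParams)
    propagate: bool = True
    include_part_of: bool = True
    force: bool = False

    def validate(self) -> None:
        if self.input_kind not in ("blast", "genelist"):
            raise ValueError("input_kind must be 'blast' or 'genelist'")
        if self.input_kind == "blast":
            if self.filter_params is None:
                raise ValueError(
                    "blast input requires filter parameters (the e-value "
                    "threshold is user-defined and mandatory)"
                )
            if self.id_map_path is None:
                raise ValueError("blast input requires an accession->symbol id map")
        if (self.corpus_path is None) == (self.unified_path is None):
            raise ValueError("exactly one of corpus_path / unified_path is required")
        for p in (self.input_path, self.obo_path, self.corpus_path,
                  self.unified_path, self.id_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_report(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")


def _out(config: PipelineConfig, name: str) -> Path:
    path = Path(config.outdir) / name
    if path.exists() and not config.force:
        raise FileExistsError(f"{path} exists; pass force=True/--force to overwrite")
    return path


def build_annotation(
    corpus_path: str, obo_path: str, out_path: str,
    propagate: bool = True, include_part_of: bool = True, force: bool = False,
) -> UnifiedAnnotation:
    """Build the unified annotation from a corpus and cache it as TSV."""
    out = Path(out_path)
    if out.exists() and not force:
        raise FileExistsError(f"{out} exists; pass force=True/--force to overwrite")
    ontology = load_obo(obo_path, include_part_of=include_part_of)
    records = read_annotation_tsv(corpus_path)
    unified = build_unified_annotation(records, ontology, propagate=propagate)
    out.parent.mkdir(parents=True, exist_ok=True)
    unified.write_tsv(out)
    if unified.rejects:
        rejects_path = out.with_suffix(".rejects.txt")
        rejects_path.write_text("\n".join(unified.rejects) + "\n")
    return unified


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the run report dictionary.

    On a stage failure the partial outputs are kept and the report is
    written with a FAILED marker naming the stage, then a
    :class:`StageError` propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ep = config.enrichment_params
    report: dict = {
        "prokgo_version": __version__,
        "input_kind": config.input_kind,
        "input_path": config.input_path,
        "obo_path": config.obo_path,
        "namespace": ep.namespace,
        "alpha": ep.alpha,
        "n_resamples": ep.n_resamples,
        "seed": ep.seed,
        "min_term_genes": ep.min_term_genes,
        "max_term_fraction": ep.max_term_fraction,
        "propagate": config.propagate,
        "include_part_of": config.include_part_of,
    }
    if config.filter_params is not None:
        report["max_evalue"] = config.filter_params.max_evalue
        report["min_query_cov"] = config.filter_params.min_query_cov
        report["min_subject_cov"] = config.filter_params.min_subject_cov

    stage = "load-ontology"
    try:
        ontology = load_obo(config.obo_path, include_part_of=config.include_part_of)
        report["n_ontology_terms"] = len(ontology.terms)

        stage = "unify-annotation"
        if config.unified_path is not None:
            report["annotation_source"] = config.unified_path
            unified = load_unified_tsv(config.unified_path, ontology)
        else:
            report["annotation_source"] = config.corpus_path
            records = read_annotation_tsv(config.corpus_path)
            unified = build_unified_annotation(
                records, ontology, propagate=config.propagate
            )
        report["pairs_retained"] = unified.n_retained
        report["pairs_excluded"] = unified.n_excluded
        report["n_unresolved_terms"] = len(unified.rejects)

        if config.input_kind == "blast":
            stage = "parse-blast"
            hits = parse_blast_tabular(config.input_path)
            report["blast_rows"] = len(hits)

            stage = "filter-blast"
            kept = filter_hits(hits, config.filter_params)
            report["blast_rows_pass_filter"] = len(kept)
            write_blast_tabular(kept, _out(config, "filtered_hits.tsv"))

            stage = "best-hit"
            best = best_hit_per_query(kept)
            report["blast_best_hits"] = len(best)
            write_blast_tabular(best, _out(config, "best_hits.tsv"))

            stage = "map-symbols"
            id_map = read_id_map(config.id_map_path)
            genes, unmapped = map_to_gene_symbols(best, id_map)
            report["genes_mapped"] = len(genes)
            report["accessions_unmapped"] = len(unmapped)
            write_gene_list(genes, _out(config, "gene_list.txt"))
            if unmapped:
                _out(config, "unmapped_accessions.txt").write_text(
                    "\n".join(unmapped) + "\n"
                )
        else:
            for skipped in ("parse-blast", "filter-blast", "best-hit", "map-symbols"):
                report[f"stage_{skipped}"] = "skipped"
            stage = "read-genelist"
            genes = read_gene_list(config.input_path)
            report["genes_input"] = len(genes)

        stage = "enrich"
        universe = GeneUniverse.from_unified(unified, ep.namespace)
        report["universe_size"] = universe.size
        results, dropped = enrich(genes, universe, ep)
        report["genes_in_universe"] = len(genes) - len(dropped)
        report["genes_dropped_out_of_universe"] = len(dropped)
        report["terms_tested"] = len(results)
        sig = significant(results, ep)
        report["terms_significant"] = len(sig)
        write_enrichment_tsv(results, _out(config, "enrichment.tsv"), ontology)

        stage = "prioritize"
        scores, pruned = prioritize(results, ontology, unified, ep)
        report["terms_after_pruning"] = len(pruned)
        report["genes_ranked"] = len(scores)
        write_ranking_tsv(scores, _out(config, "gene_ranking.tsv"))

        report["status"] = "OK"
        _write_report(report, outdir / "run_report.txt")
        return report
    except Exception as exc:
        report["status"] = f"FAILED at stage {stage}"
        try:
            _write_report(report, outdir / "run_report.txt")
        except OSError:
            pass
        raise StageError(stage, exc) from exc
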