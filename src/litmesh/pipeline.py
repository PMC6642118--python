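"""End-to-end orchestration of the five pipeline tasks.

A run walks: corpus build -> MeSH prioritisation -> gene network ->
(unless bypassed) series ingestion + probe collapse + stratification ->
core analyses, optionally followed by a term-set similarity report.
Every stage writes static TSV/JSON/GraphML outputs into one run
directory, and a machine-readable manifest records inputs (as SHA-256
digests), outputs, warnings, the seed, and the analyses performed per
publication/series pair.  With fixed inputs and seed a run is
byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .analyses import (
    build_gene_network,
    cluster_samples,
    pca,
    top_variable_genes,
    write_network,
    zscore_rows,
)
from .expression import (
    collapse_probes,
    parse_series_matrix,
    read_platform_table,
    stratify_samples,
)
from .literature import (
    Corpus,
    build_corpus_from_pmids,
    limit_corpus,
    parse_records,
    write_corpus_jsonl,
    write_corpus_tsv,
)
from .mesh import parse_mesh
from .prioritise import prioritise
from .similarity import SimilarityConfig, MEASURES, set_similarity, significance_flag

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

CORE_ANALYSES = ("pca", "variable_gene_zscores", "sample_clustering", "gene_network")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``query`` / ``pmid_file`` selects the operating mode;
    in both cases records are drawn from the offline record store at
    ``records_path`` (the live-retrieval adapter is out of band).  The
    email is recorded for courtesy headers of any live adapter.
    """

    records_path: str
    mesh_path: str
    background_path: str
    out_dir: str
    query: str | None = None
    pmid_file: str | None = None
    email: str = ""
    max_records: int | None = None
    skip_expression: bool = False
    seed: int = 0
    interactome_path: str | None = None
    gene_scores_path: str | None = None
    gene_annotations_path: str | None = None
    series_matrix_path: str | None = None
    platform_path: str | None = None
    top_n_genes: int = 20
    pca_components: int = 2
    similarity_terms_a: str | None = None
    similarity_terms_b: str | None = None
    similarity_measure: str = "shortest_path"

    def __post_init__(self) -> None:
        if (self.query is None) == (self.pmid_file is None):
            raise ValueError("exactly one of query / pmid_file must be set")
        if self.max_records is not None and self.max_records < 1:
            raise ValueError("max_records must be >= 1")
        if self.similarity_measure not in MEASURES:
            raise ValueError(f"unknown similarity measure {self.similarity_measure!r}")

    @property
    def mode(self) -> str:
        return "query" if self.query is not None else "pmid-list"


@dataclass
class RunManifest:
    """Machine-readable account of one run."""

    mode: str
    seed: int
    version: str
    email: str
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)       # relative paths
    analyses: dict[str, list[str]] = field(default_factory=dict)  # "pmid:gse" -> labels
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        payload = asdict(self)
        payload["outputs"] = sorted(set(payload["outputs"]))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_two_column_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def _read_term_file(path: str | Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the pipeline described by *config*; returns the manifest.

    A stage failure aborts the run with the stage name; outputs written
    before the failure are retained and the manifest carries a failure
    marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        mode=config.mode, seed=config.seed, version=__version__, email=config.email
    )
    for p in (
        config.records_path,
        config.mesh_path,
        config.background_path,
        config.interactome_path,
        config.gene_scores_path,
        config.gene_annotations_path,
        config.series_matrix_path,
        config.platform_path,
        config.pmid_file,
        config.similarity_terms_a,
        config.similarity_terms_b,
    ):
        if p:
            manifest.inputs[str(p)] = _sha256(p)

    stage = "corpus"
    try:
        # -- corpus ------------------------------------------------------
        corpus = parse_records(config.records_path, dialect="json")
        if config.mode == "pmid-list":
            wanted = _read_term_file(config.pmid_file)
            store = {r.pmid: r for r in corpus}
            corpus, missing = build_corpus_from_pmids(wanted, store)
            for pmid in missing:
                manifest.warnings.append(f"pmid {pmid} unresolvable in record store")
        else:
            corpus = Corpus(records=list(corpus.records), query=config.query,
                            source_tag=corpus.source_tag)
        if config.max_records is not None:
            corpus = limit_corpus(corpus, config.max_records)

        # -- prioritisation ---------------------------------------------
        stage = "prioritisation"
        tree = parse_mesh(config.mesh_path, dialect="tsv")
        background = _read_two_column_tsv(config.background_path)
        result = prioritise(corpus, tree, background)
        result.write_tsv(out / "prioritised_terms.tsv")
        manifest.outputs.append("prioritised_terms.tsv")
        for t in result.unresolved_terms:
            manifest.warnings.append(f"heading not in vocabulary: {t}")
        for t in result.imputed_terms:
            manifest.warnings.append(f"background median imputed for term: {t}")

        # -- gene network -------------------------------------------------
        stage = "gene_network"
        network_built = False
        if config.gene_scores_path and config.interactome_path:
            gene_scores = _read_two_column_tsv(config.gene_scores_path)
            inter_df = pd.read_csv(config.interactome_path, sep="\t", dtype={0: str, 1: str})
            interactome = [
                (str(a), str(b), float(s))
                for a, b, s in inter_df.itertuples(index=False)
            ]
            annotations: dict[str, set[str]] = {}
            if config.gene_annotations_path:
                ann_df = pd.read_csv(config.gene_annotations_path, sep="\t", dtype=str)
                for pmid, genes in ann_df.itertuples(index=False):
                    annotations[str(pmid)] = set(str(genes).split(";")) if genes else set()
            g = build_gene_network(gene_scores, interactome, corpus, annotations)
            write_network(
                g,
                out / "network.graphml",
                out / "network_nodes.tsv",
                out / "network_edges.tsv",
            )
            manifest.outputs += ["network.graphml", "network_nodes.tsv", "network_edges.tsv"]
            network_built = True

        # -- expression ---------------------------------------------------
        expression_done = False
        if not config.skip_expression and config.series_matrix_path:
            stage = "expression"
            platform = (
                read_platform_table(config.platform_path)
                if config.platform_path
                else None
            )
            series = parse_series_matrix(config.series_matrix_path, platform=platform)
            if series.n_missing:
                manifest.warnings.append(
                    f"{series.n_missing} non-numeric expression cells set missing"
                )
            series.pdata.to_csv(out / "pdata.tsv", sep="\t")
            manifest.outputs.append("pdata.tsv")
            if series.tdata is None:
                raise ValueError("no platform probe->gene annotation supplied")
            gene_matrix, dropped = collapse_probes(series.edata, series.tdata)
            if dropped:
                manifest.warnings.append(f"{dropped} probes without gene mapping dropped")
            gene_matrix.to_csv(out / "gene_matrix.tsv", sep="\t", float_format="%.6g")
            manifest.outputs.append("gene_matrix.tsv")
            groups = stratify_samples(series.pdata)
            groups.to_frame().to_csv(out / "sample_groups.tsv", sep="\t", index=False)
            manifest.outputs.append("sample_groups.tsv")

            # -- core analyses -------------------------------------------
            stage = "core_analyses"
            pres = pca(gene_matrix, k=config.pca_components)
            pres.write_tsv(out / "pca_scores.tsv", out / "pca_explained.tsv")
            manifest.outputs += ["pca_scores.tsv", "pca_explained.tsv"]
            top = top_variable_genes(gene_matrix, config.top_n_genes)
            z = zscore_rows(gene_matrix.loc[top])
            z.to_csv(out / "zscore_matrix.tsv", sep="\t", float_format="%.6g")
            manifest.outputs.append("zscore_matrix.tsv")
            clust = cluster_samples(gene_matrix.loc[top])
            (out / "sample_clusters.json").write_text(clust.to_json() + "\n")
            manifest.outputs.append("sample_clusters.json")
            expression_done = True

        # -- similarity report -------------------------------------------
        if config.similarity_terms_a and config.similarity_terms_b:
            stage = "similarity"
            set_a = _read_term_file(config.similarity_terms_a)
            set_b = _read_term_file(config.similarity_terms_b)
            score = set_similarity(tree, set_a, set_b, config.similarity_measure)
            with open(out / "similarity_report.tsv", "w", encoding="utf-8") as fh:
                fh.write("measure\tscore\tsignificant\n")
                fh.write(
                    f"{config.similarity_measure}\t{score:.6f}\t"
                    f"{str(significance_flag(score)).lower()}\n"
                )
            manifest.outputs.append("similarity_report.tsv")

        # -- corpus outputs + per-tuple analysis labels -------------------
        stage = "corpus_outputs"
        labels = list(CORE_ANALYSES if (expression_done and network_built) else
                      (("gene_network",) if network_built else ()))
        for rec in corpus:
            for gse in rec.gse_codes:
                per_tuple = [
                    lab for lab in labels
                    if lab == "gene_network" or not config.skip_expression
                ]
                manifest.analyses[f"{rec.pmid}:{gse}"] = per_tuple
                rec.analyses = sorted(set(rec.analyses) | set(per_tuple))
        write_corpus_jsonl(corpus, out / "corpus.jsonl")
        write_corpus_tsv(corpus, out / "corpus.tsv")
        manifest.outputs += ["corpus.jsonl", "corpus.tsv"]
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.warnings.append(f"stage {stage} failed: {exc}")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
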