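"""End-to-end pipeline: corpus -> filtered matrix -> correlation/PCA/clusters
-> relatedness, with every artifact written to the output directory and a
manifest recording the config hash and seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from chemocoex import io
from chemocoex.clustering import (
    ClusterAssignment,
    PcaResult,
    clara,
    hclust_order,
    pca_scores,
    pearson_matrix,
    select_k,
    silhouette_width,
    standardize_genes,
)
from chemocoex.config import PipelineConfig
from chemocoex.filtering import (
    ExpressionMatrix,
    RetentionStats,
    assemble_matrix,
    four_step_filter,
    retention_summary,
)
from chemocoex.panel import GenePanel, default_panel, load_panel, subset
from chemocoex.relatedness import RelatednessSummary, compare_families, default_families, load_families
from chemocoex.simulate import Corpus, corpus_summary, generate_corpus, default_corpus_config

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    corpus: Corpus
    panel: GenePanel
    matrix: ExpressionMatrix
    filtered: ExpressionMatrix
    stats: RetentionStats
    correlation: pd.DataFrame
    heatmap_order: list[str]
    pca: PcaResult
    clusters: ClusterAssignment
    chosen_k: int
    silhouette_table: pd.DataFrame
    relatedness: list[RelatednessSummary]
    out_dir: Path


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Deterministic given (inputs, seed): the corpus simulation and CLARA
    subsampling draw from named substreams of the single config seed.
    Partial outputs written before a failing stage are retained on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    analysis_panel = subset(panel, config.panel_categories) if config.panel_categories else panel

    if config.corpus_path:
        corpus = _stage("read_corpus")(io.read_corpus)(
            config.corpus_path, dialect=config.corpus_dialect, metadata=config.corpus_metadata
        )
    else:
        gen_cfg = default_corpus_config(panel, seed=config.seed)
        corpus = _stage("simulate")(generate_corpus)(gen_cfg)
        io.write_corpus(corpus, out / "corpus.tsv")
    io.write_json(corpus_summary(corpus), out / "corpus_summary.json")

    matrix = _stage("assemble")(assemble_matrix)(
        corpus,
        analysis_panel,
        species=config.species,
        tissue=config.tissue,
        disease=config.disease,
        exclude_tumour=config.exclude_tumour,
    )
    io.write_matrix(matrix, out / "matrix_raw.tsv")

    filtered, stats = _stage("filter")(four_step_filter)(
        matrix, t_gene1=config.t_gene1, t_assay=config.t_assay, t_gene2=config.t_gene2
    )
    io.write_matrix(filtered, out / "matrix_filtered.tsv")
    (out / "retention.txt").write_text(retention_summary(stats) + "\n", encoding="utf-8")
    logger.info("filtration:\n%s", retention_summary(stats))

    corr = _stage("correlate")(pearson_matrix)(filtered)
    io.write_correlation(corr, out / "correlation.tsv")
    order = hclust_order(corr)
    (out / "heatmap_order.txt").write_text("\n".join(order) + "\n", encoding="utf-8")

    pca = _stage("pca")(pca_scores)(filtered, m=config.pca_components)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")

    z = _stage("standardize")(standardize_genes)(filtered)
    if config.k is None:
        chosen_k, sil_table = _stage("select_k")(select_k)(
            z,
            range(config.k_range[0], config.k_range[1] + 1),
            n_samples=config.n_samples,
            sample_size=config.sample_size,
            seed=config.seed,
        )
    else:
        chosen_k = config.k
        sil_table = pd.DataFrame({"k": [], "mean_silhouette": []})
    clusters = _stage("cluster")(clara)(
        z, chosen_k, n_samples=config.n_samples, sample_size=config.sample_size, seed=config.seed
    )
    io.write_clusters(clusters, out / "clusters.tsv")
    if len(sil_table):
        io.write_silhouette_table(sil_table, out / "silhouette.tsv")
    logger.info("selected k=%d clusters", chosen_k)

    families = load_families(config.families_path) if config.families_path else default_families()
    scope = {"species": config.species, "tissue": config.tissue, "disease": config.disease}
    summaries = _stage("relatedness")(compare_families)(corr, families, scope=scope)
    io.write_relatedness(summaries, out / "relatedness.tsv")

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_genes_filtered": filtered.values.shape[0],
        "n_assays_filtered": filtered.values.shape[1],
        "chosen_k": chosen_k,
    }
    io.write_json(manifest, out / "manifest.json")

    return PipelineResult(
        corpus=corpus,
        panel=panel,
        matrix=matrix,
        filtered=filtered,
        stats=stats,
        correlation=corr,
        heatmap_order=order,
        pca=pca,
        clusters=clusters,
        chosen_k=chosen_k,
        silhouette_table=sil_table,
        relatedness=summaries,
        out_dir=out,
    )
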