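"""Core analyses on gene-level expression plus the literature gene network.

* PCA of samples over gene-mean-centred expression (SVD-based, with a
  deterministic sign convention), to expose the dominant sources of
  variation among samples.
* Most-variable-gene selection and per-gene z-scoring, the inputs of the
  usual expression heatmap.
* Agglomerative sample clustering (Euclidean distance, complete linkage
  by default) with a deterministic leaf order.
* A gene network built by overlapping literature-associated genes on a
  scored interactome, with each retained edge annotated by its
  co-citation count — the number of corpus publications whose annotated
  gene set contains both endpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .literature import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "ClusterResult",
    "pca",
    "top_variable_genes",
    "zscore_rows",
    "cluster_samples",
    "build_gene_network",
    "write_network",
]


@dataclass
class PcaResult:
    """Sample scores, per-component explained-variance fractions and
    gene loadings of a principal-component decomposition."""

    scores: pd.DataFrame          # samples x k
    explained_ratio: np.ndarray   # k fractions of *total* variance
    loadings: pd.DataFrame        # genes x k
    k: int
    n_imputed: int = 0

    def write_tsv(self, scores_path, explained_path) -> None:
        self.scores.to_csv(scores_path, sep="\t", float_format="%.8g")
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.k)],
                "explained_ratio": self.explained_ratio,
            }
        ).to_csv(explained_path, sep="\t", index=False, float_format="%.8g")


def _impute_gene_means(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing cells imputed to gene means", n_missing)
        means = matrix.mean(axis=1)
        matrix = matrix.apply(lambda col: col.fillna(means))
    return matrix, n_missing


def pca(matrix: pd.DataFrame, k: int = 2) -> PcaResult:
    """PCA of samples over a genes x samples matrix.

    Rows (genes) are mean-centred; no gene scaling is applied (z-scoring
    is a separate explicit step).  Missing cells are imputed to the gene
    mean first.  Component signs are fixed by making each component's
    largest-magnitude gene loading positive, so results are reproducible
    across runs and sample orderings.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(matrix.shape)}")
    filled, n_imputed = _impute_gene_means(matrix)
    x = filled.to_numpy(dtype=float)
    centred = x - x.mean(axis=1, keepdims=True)
    # samples as observations: decompose the samples x genes matrix
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("matrix has zero variance")
    for j in range(min(k, len(s))):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_ratio=(s[:k] ** 2) / total,
        loadings=pd.DataFrame(
            vt[:k].T, index=matrix.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        k=k,
        n_imputed=n_imputed,
    )


def top_variable_genes(matrix: pd.DataFrame, n: int) -> list[str]:
    """Genes ordered by sample variance descending (ties by name), first
    min(n, #genes) returned."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    return order[: min(n, len(order))]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardisation: (x - row mean) / row sample-sd.

    Rows with fewer than 2 observed values or zero variance become
    all-zero with a warning; missing cells stay missing.
    """
    out = matrix.astype(float).copy()
    for gene in matrix.index:
        row = out.loc[gene]
        n_obs = int(row.notna().sum())
        sd = row.std(ddof=1)
        if n_obs < 2 or not sd > 0:
            logger.warning("row %s has no variance; z-scores set to 0", gene)
            out.loc[gene] = row.where(row.isna(), 0.0)
        else:
            out.loc[gene] = (row - row.mean()) / sd
    return out


@dataclass
class ClusterResult:
    """Deterministic agglomerative clustering of samples."""

    order: list[str]          # leaf order, left to right
    linkage: np.ndarray       # scipy linkage matrix over `samples`
    samples: list[str]        # name-sorted leaf labels the linkage refers to
    metric: str
    method: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "samples": self.samples,
                "metric": self.metric,
                "method": self.method,
                "merges": [
                    {
                        "left": int(a),
                        "right": int(b),
                        "height": round(float(h), 10),
                        "size": int(n),
                    }
                    for a, b, h, n in self.linkage
                ],
            },
            indent=1,
            sort_keys=True,
        )


def cluster_samples(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of samples (columns).

    Samples are name-sorted before linkage so the merge tree does not
    depend on input column order; missing cells are imputed to gene
    means first.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    filled, _ = _impute_gene_means(matrix)
    samples = sorted(str(c) for c in filled.columns)
    x = filled[samples].to_numpy(dtype=float).T
    z = hierarchy.linkage(pdist(x, metric=metric), method=method)
    order = [samples[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(order=order, linkage=z, samples=samples, metric=metric, method=method)


def build_gene_network(
    gene_scores: Mapping[str, float],
    interactome: Iterable[tuple[str, str, float]],
    corpus: Corpus | None = None,
    gene_annotations: Mapping[str, Iterable[str]] | None = None,
) -> nx.Graph:
    """Overlap literature-scored genes on a scored interactome.

    Nodes are the scored genes (node attribute ``score``); edges are the
    interactome pairs with both endpoints scored, weighted by the
    interactome score (edge attribute ``weight``) and annotated with the
    co-citation count over the corpus (edge attribute ``cocitation``).
    Self-pairs are ignored; the induced edge set may be empty.
    """
    if not gene_scores:
        raise ValueError("gene_scores must be non-empty")
    g = nx.Graph()
    for gene in sorted(gene_scores):
        g.add_node(gene, score=float(gene_scores[gene]))
    pub_sets: list[frozenset[str]] = []
    if corpus is not None and gene_annotations is not None:
        for rec in corpus:
            genes = gene_annotations.get(rec.pmid)
            if genes:
                pub_sets.append(frozenset(genes))
    for a, b, score in interactome:
        if a == b or a not in g or b not in g:
            continue
        cocit = sum(1 for s in pub_sets if a in s and b in s)
        g.add_edge(*sorted((a, b)), weight=float(score), cocitation=cocit)
    return g


def write_network(
    g: nx.Graph,
    graphml_path: Union[str, Path],
    nodes_path: Union[str, Path],
    edges_path: Union[str, Path],
) -> None:
    """Write the network as GraphML plus node/edge TSVs."""
    nx.write_graphml(g, str(graphml_path), named_key_ids=True)
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for gene in sorted(g.nodes):
            fh.write(f"{gene}\t{g.nodes[gene]['score']:g}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\tcocitation\n")
        for a, b in sorted(g.edges):
            d = g.edges[a, b]
            fh.write(f"{a}\t{b}\t{d['weight']:g}\t{d['cocitation']}\n")
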