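"""PCA, variable genes, z-scores, clustering and the gene network."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from litmesh.analyses import (
    build_gene_network,
    cluster_samples,
    pca,
    top_variable_genes,
    zscore_rows,
)
from litmesh.literature import Corpus, PubRecord


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestPca:
    def test_scores_match_eigendecomposition_oracle(self):
        m = _matrix([[1.0, 2.0, 6.0], [2.0, 8.0, 4.0]])
        res = pca(m, k=2)
        centred = (m.T - m.mean(axis=1)).to_numpy()  # samples x genes
        cov = centred.T @ centred
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(np.sort(res.explained_ratio)[::-1],
                           evals / evals.sum(), atol=1e-9)
        for j in range(2):
            got = res.scores.to_numpy()[:, j]
            want = centred @ evecs[:, j]
            assert np.allclose(got, want, atol=1e-9) or np.allclose(got, -want, atol=1e-9)

    def test_duplicated_samples_coincide_in_score_space(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3))
        m = _matrix(np.hstack([base, base[:, [0]]]),
                    samples=["a", "b", "c", "a2"])
        res = pca(m, k=2)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["a2"], atol=1e-9)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(6, 4)))
        res = pca(m, k=4)
        centred = (m.T - m.mean(axis=1)).to_numpy()
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(approx, centred, atol=1e-9)
        assert res.explained_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sample_reordering_invariance_under_sign_rule(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(5, 6)))
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        a, b = pca(m, k=2), pca(m[perm], k=2)
        for s in m.columns:
            assert np.allclose(a.scores.loc[s], b.scores.loc[s], atol=1e-9)

    def test_k_exceeding_rank_is_error(self):
        with pytest.raises(ValueError):
            pca(_matrix([[1.0, 2.0], [3.0, 4.0]]), k=3)

    def test_missing_cells_imputed_to_gene_mean(self):
        m = _matrix([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        res = pca(m, k=1)
        assert res.n_imputed == 1
        assert np.isfinite(res.scores.to_numpy()).all()


class TestVariableGenesAndZscores:
    def test_sorted_by_variance_then_name(self):
        m = _matrix([[0, 5, 0], [0, 1, 0], [0, 3, 0]], genes=["a", "b", "c"])
        assert top_variable_genes(m, 2) == ["a", "c"]

    def test_clamped_to_gene_count(self):
        m = _matrix(np.eye(3))
        assert len(top_variable_genes(m, 100)) == 3

    def test_constant_gene_ranks_last(self):
        m = _matrix([[1, 1, 1], [0, 9, 0]], genes=["flat", "varying"])
        assert top_variable_genes(m, 2)[-1] == "flat"

    def test_zscore_row_example(self):
        z = zscore_rows(_matrix([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            z = zscore_rows(_matrix([[4.0, 4.0, 4.0]]))
        assert np.allclose(z.to_numpy()[0], 0.0)
        assert any("no variance" in m for m in caplog.messages)

    def test_rows_standardised_and_idempotent(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(8, 6)))
        z = zscore_rows(m)
        assert np.abs(z.mean(axis=1)).max() <= 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1.0).max() <= 1e-12
        assert np.allclose(zscore_rows(z).to_numpy(), z.to_numpy(), atol=1e-12)


def brute_force_complete_linkage(matrix: pd.DataFrame):
    """O(n^3) agglomeration oracle; returns merge heights and partitions."""
    samples = sorted(matrix.columns)
    points = {s: matrix[s].to_numpy(dtype=float) for s in samples}
    clusters: list[frozenset[str]] = [frozenset([s]) for s in samples]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            d = max(
                float(np.linalg.norm(points[a] - points[b]))
                for a in clusters[i]
                for b in clusters[j]
            )
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((d, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        m = _matrix([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]], samples=["a", "b", "c"])
        res = cluster_samples(m)
        assert res.linkage[0, 2] == 0.0
        first = {res.samples[int(res.linkage[0, 0])], res.samples[int(res.linkage[0, 1])]}
        assert first == {"a", "b"}

    def test_merge_tree_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(5, 4)), samples=list("dacb"))
        res = cluster_samples(m)
        oracle = brute_force_complete_linkage(m)
        assert len(res.linkage) == len(oracle)
        # reconstruct partitions from the scipy linkage
        clusters = {i: frozenset([s]) for i, s in enumerate(res.samples)}
        for row_idx, (a, b, h, _) in enumerate(res.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[len(res.samples) + row_idx] = merged
            d_o, merged_o = oracle[row_idx]
            assert h == pytest.approx(d_o, abs=1e-9)
            assert merged == merged_o

    def test_column_permutation_does_not_change_tree(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(6, 5)))
        perm = ["s4", "s2", "s0", "s3", "s1"]
        a, b = cluster_samples(m), cluster_samples(m[perm])
        assert a.order == b.order
        assert np.allclose(a.linkage, b.linkage)


class TestGeneNetwork:
    def test_endpoint_filter(self):
        g = build_gene_network(
            {"G1": 1.0, "G2": 2.0, "G3": 0.5},
            [("G1", "G2", 0.7), ("G2", "G4", 0.9)],
        )
        assert set(g.nodes) == {"G1", "G2", "G3"}
        assert set(g.edges) == {("G1", "G2")}
        assert g.edges["G1", "G2"]["weight"] == 0.7

    def test_cocitation_enumeration(self):
        corpus = Corpus(
            records=[PubRecord(pmid=p) for p in ("P1", "P2", "P3")]
        )
        ann = {"P1": {"G1", "G2"}, "P2": {"G1", "G2"}, "P3": {"G1"}}
        g = build_gene_network(
            {"G1": 1.0, "G2": 1.0}, [("G1", "G2", 0.5)], corpus, ann
        )
        assert g.edges["G1", "G2"]["cocitation"] == 2

    def test_no_overlap_gives_isolated_scored_nodes(self):
        g = build_gene_network({"G1": 3.0, "G2": 1.0}, [("X", "Y", 0.9)])
        assert g.number_of_edges() == 0
        assert g.nodes["G1"]["score"] == 3.0

    def test_induced_subgraph_equality_and_cocitation_bounds(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(12)]
        scores = {g: float(rng.uniform(0, 5)) for g in genes[:8]}
        inter = []
        for a, b in combinations(genes, 2):
            if rng.random() < 0.4:
                inter.append((a, b, float(rng.uniform(0, 1))))
        records = [PubRecord(pmid=str(i)) for i in range(40)]
        ann = {
            str(i): set(rng.choice(genes[:8], size=3, replace=False)) for i in range(40)
        }
        g = build_gene_network(scores, inter, Corpus(records=records), ann)
        naive = {
            tuple(sorted((a, b)))
            for a, b, _ in inter
            if a in scores and b in scores and a != b
        }
        assert set(g.edges) == naive
        citations = {x: sum(1 for s in ann.values() if x in s) for x in genes[:8]}
        for a, b in g.edges:
            expected = sum(1 for s in ann.values() if a in s and b in s)
            assert g.edges[a, b]["cocitation"] == expected
            assert g.edges[a, b]["cocitation"] <= min(citations[a], citations[b])

    def test_empty_scores_is_error(self):
        with pytest.raises(ValueError):
            build_gene_network({}, [])
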