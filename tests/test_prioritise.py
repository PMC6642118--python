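"""Three-criteria ranking and Robust Rank Aggregation scoring.

The RRA beta-score is checked against an independent direct-summation
oracle (binomial mass summed with exact integer binomials) and against a
seeded Monte-Carlo null for calibration.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from litmesh.literature import Corpus, PubRecord, mesh_term_counts
from litmesh.mesh import parse_mesh
from litmesh.prioritise import (
    RankedList,
    normalize_ranks,
    prioritise,
    rank_global_abundance,
    rank_local_abundance,
    rank_specificity,
    rra_score,
    rra_score_many,
)


def beta_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k), X ~ Binomial(n, p), by exact mass summation."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def rra_oracle(r) -> tuple[float, float]:
    r_sorted = sorted(r)
    n = len(r_sorted)
    betas = [beta_tail_oracle(k, n, r_sorted[k - 1]) for k in range(1, n + 1)]
    rho = min(betas)
    return rho, min(1.0, rho * n)


TREE_TSV = (
    "D01\tAorta\tA01\n"
    "D02\tBrain\tA01.100\n"
    "D03\tCortex\tA01.100.200\n"
    "D04\tDura\tA01.100.300\n"
    "D05\tEar\tA01.200\n"
)


@pytest.fixture()
def small_tree():
    return parse_mesh(io.StringIO(TREE_TSV), "tsv")


class TestCriterionRankings:
    def test_specificity_deeper_first(self, small_tree):
        rl = rank_specificity(["D01", "D03", "D05"], small_tree)
        assert rl.ordering == ["D03", "D05", "D01"]

    def test_specificity_tie_broken_by_name(self, small_tree):
        rl = rank_specificity(["D04", "D03"], small_tree)  # both depth 3
        assert rl.ordering == ["D03", "D04"]  # Cortex < Dura

    def test_local_abundance_descending_with_name_ties(self):
        rl = rank_local_abundance({"T1": 5, "T2": 2, "T3": 2})
        assert rl.ordering == ["T1", "T2", "T3"]
        rl = rank_local_abundance({"B": 1, "A": 1, "C": 1})
        assert rl.ordering == ["A", "B", "C"]

    def test_global_abundance_rarer_first(self):
        rl, imputed = rank_global_abundance(["T1", "T2"], {"T1": 10**6, "T2": 10**3})
        assert rl.ordering == ["T2", "T1"]
        assert imputed == []

    def test_global_missing_term_gets_median(self):
        bg = {"A": 10.0, "B": 100.0, "C": 1000.0}  # median 100
        rl, imputed = rank_global_abundance(["A", "X", "C"], bg)
        assert imputed == ["X"]
        assert rl.ordering == ["A", "X", "C"]

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            RankedList("specificity", ["T", "T"])


class TestNormalizeRanks:
    def test_position_over_size(self):
        lists = [RankedList("local_abundance", [f"T{i}" for i in range(100)])]
        vec = normalize_ranks(lists, [f"T{i}" for i in range(100)])
        assert vec["T0"][0] == pytest.approx(0.01)
        assert vec["T99"][0] == pytest.approx(1.0)

    def test_absent_term_gets_worst_rank(self):
        lists = [RankedList("specificity", ["A", "B"])]
        vec = normalize_ranks(lists, ["A", "B", "C"])
        assert vec["C"][0] == 1.0


class TestRraScore:
    def test_degenerate_worst_ranks(self):
        rho, p, _ = rra_score([1.0, 1.0, 1.0])
        assert rho == 1.0 and p == 1.0

    def test_exact_three_list_example(self):
        rho, p, k = rra_score([0.1, 0.2, 0.3])
        assert rho == pytest.approx(0.027, abs=1e-12)
        assert p == pytest.approx(0.081, abs=1e-12)
        assert k == 3

    def test_component_bounds_enforced(self):
        with pytest.raises(ValueError):
            rra_score([0.0, 0.5])
        with pytest.raises(ValueError):
            rra_score([0.5, 1.5])

    def test_agrees_with_direct_summation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 11))
            r = rng.uniform(1e-9, 1.0, size=n)
            rho, p, _ = rra_score(r)
            rho_o, p_o = rra_oracle(r)
            assert abs(rho - rho_o) <= 1e-12
            assert abs(p - p_o) <= 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6),
        st.data(),
    )
    def test_improving_a_rank_never_increases_rho(self, r, data):
        i = data.draw(st.integers(0, len(r) - 1))
        better = data.draw(st.floats(0.0005, r[i]))
        rho_before, _, _ = rra_score(r)
        r2 = list(r)
        r2[i] = better
        rho_after, _, _ = rra_score(r2)
        assert rho_after <= rho_before + 1e-12

    def test_null_calibration_is_conservative(self):
        rng = np.random.default_rng(2024)
        draws = rng.uniform(1e-12, 1.0, size=(100_000, 3))
        p = rra_score_many(draws)
        for alpha in (0.01, 0.05):
            frac = float((p <= alpha).mean())
            stderr = math.sqrt(alpha * (1 - alpha) / draws.shape[0])
            assert frac <= alpha + 3 * stderr


def brute_force_prioritise(corpus, tree, background):
    """Independently coded scorer: ranks + exact-summation beta-scores."""
    counts: dict[str, int] = {}
    for rec in corpus:
        for term in {tree.resolve(t) for t in rec.mesh_headings}:
            if term is not None:
                counts[term] = counts.get(term, 0) + 1
    universe = sorted(counts)
    names = {u: tree.name(u) for u in universe}
    bg = {tree.resolve(k): v for k, v in background.items() if tree.resolve(k)}
    med = float(np.median(sorted(bg.values())))
    by_depth = sorted(universe, key=lambda u: (-tree.descriptor_depth(u, "max"), names[u]))
    by_local = sorted(universe, key=lambda u: (-counts[u], names[u]))
    by_global = sorted(universe, key=lambda u: (bg.get(u, med), names[u]))
    rows = {}
    n_u = len(universe)
    for u in universe:
        r = [
            (lst.index(u) + 1) / n_u
            for lst in (by_depth, by_local, by_global)
        ]
        rho, p = rra_oracle(r)
        rows[u] = (r, rho, p)
    order = sorted(universe, key=lambda u: (rows[u][2], rows[u][1], names[u]))
    return order, rows


class TestPrioritise:
    def _fixture_corpus(self):
        # 10 records over 12 terms of the small tree universe
        tsv = "".join(
            f"D{i:02d}\tname{i:02d}\t{pos}\n"
            for i, pos in enumerate(
                [
                    "A01", "A01.100", "A01.100.200", "A01.100.300",
                    "A01.200", "A01.200.100", "A01.200.100.100",
                    "B02", "B02.100", "B02.100.100", "B02.200", "B02.300",
                ]
            )
        )
        tree = parse_mesh(io.StringIO(tsv), "tsv")
        rng = np.random.default_rng(7)
        uis = sorted(tree.descriptors)
        records = []
        for i in range(10):
            n = int(rng.integers(2, 6))
            headings = sorted(rng.choice(uis, size=n, replace=False))
            records.append(PubRecord(pmid=str(i + 1), mesh_headings=list(headings)))
        background = {u: int(rng.integers(100, 10**6)) for u in uis}
        return Corpus(records=records), tree, background

    def test_matches_brute_force_scorer_exactly(self):
        corpus, tree, background = self._fixture_corpus()
        result = prioritise(corpus, tree, background)
        order, rows = brute_force_prioritise(corpus, tree, background)
        assert list(result.table["term"]) == order
        for _, row in result.table.iterrows():
            r, rho, p = rows[row["term"]]
            assert row["rho"] == pytest.approx(rho, abs=1e-12)
            assert row["p_corrected"] == pytest.approx(p, abs=1e-12)
            assert [row["r_specificity"], row["r_local"], row["r_global"]] == pytest.approx(r)

    def test_term_first_in_all_lists_has_smallest_p(self, small_tree):
        # D03 is deepest (with name ties resolved in its favour), most
        # locally abundant and globally rarest -> must come out on top
        records = [
            PubRecord(pmid=str(i + 1), mesh_headings=["D03"] + (["D01"] if i < 2 else []))
            for i in range(6)
        ]
        background = {"D01": 10**6, "D02": 10**5, "D03": 10, "D04": 10**4, "D05": 10**5}
        corpus = Corpus(records=records)
        result = prioritise(corpus, small_tree, background)
        assert result.table.iloc[0]["term"] == "D03"
        assert result.table.iloc[0]["p_corrected"] == result.table["p_corrected"].min()

    def test_single_term_universe_scores_one(self, small_tree):
        corpus = Corpus(records=[PubRecord(pmid="1", mesh_headings=["D02"])])
        result = prioritise(corpus, small_tree, {"D02": 100})
        assert result.table.iloc[0]["p_corrected"] == 1.0

    def test_unresolvable_headings_reported(self, small_tree):
        corpus = Corpus(
            records=[PubRecord(pmid="1", mesh_headings=["D02", "NotATerm"])]
        )
        result = prioritise(corpus, small_tree, {"D02": 100})
        assert result.unresolved_terms == ["NotATerm"]

    def test_corpus_without_headings_is_error(self, small_tree):
        with pytest.raises(ValueError):
            prioritise(Corpus(records=[PubRecord(pmid="1")]), small_tree, {"D02": 1})
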