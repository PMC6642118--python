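"""MeSH term prioritisation by three-criteria Robust Rank Aggregation.

Terms annotating a corpus are ranked under three separate criteria —

* **specificity**: deeper placement in the MeSH hierarchy is better;
* **local abundance**: annotating more corpus records is better;
* **global abundance**: rarer across all of PubMed is better —

and the three orderings are fused with Robust Rank Aggregation (RRA).
For each term, its positions are normalised to ``r_i = rank_i / N_i``
(worst rank 1.0 assigned when absent from a list); the sorted vector
``r_(1) <= ... <= r_(n)`` is scored by the binomial tail
``beta_k = P(X >= k)`` with ``X ~ Binomial(n, r_(k))``, i.e. the
probability that at least k of n independent uniform ranks fall at or
below ``r_(k)``.  The score ``rho = min_k beta_k`` is Bonferroni
corrected by the number of order statistics: ``p = min(1, rho * n)``.
Small p means the term is ranked consistently better across the criteria
than expected under random allocation.

The three criterion directions implement a TF-IDF-like notion of a
"specific, topic-enriched, globally rare" heading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .literature import Corpus, mesh_term_counts
from .mesh import MeshTree

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "PrioritisationResult",
    "rank_specificity",
    "rank_local_abundance",
    "rank_global_abundance",
    "normalize_ranks",
    "rra_score",
    "prioritise",
]

CRITERIA = ("specificity", "local_abundance", "global_abundance")


@dataclass
class RankedList:
    """One criterion's ordering of terms, best first, no duplicates."""

    criterion: str
    ordering: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError("ordering contains duplicate terms")

    @property
    def size(self) -> int:
        return len(self.ordering)


def rank_specificity(terms: Iterable[str], tree: MeshTree) -> RankedList:
    """Order terms (descriptor uis) by deepest placement, descending.

    Ties are broken by descriptor name ascending.
    """
    uis = list(terms)
    if not uis:
        raise ValueError("no terms to rank")
    ordered = sorted(uis, key=lambda u: (-tree.descriptor_depth(u, "max"), tree.name(u)))
    return RankedList("specificity", ordered)


def rank_local_abundance(
    counts: Mapping[str, int], names: Mapping[str, str] | None = None
) -> RankedList:
    """Order terms by corpus record count, descending; ties by name."""
    if not counts:
        raise ValueError("counts must be non-empty")
    label = (lambda t: names.get(t, t)) if names is not None else (lambda t: t)
    ordered = sorted(counts, key=lambda t: (-counts[t], label(t)))
    return RankedList("local_abundance", ordered)


def rank_global_abundance(
    terms: Iterable[str],
    background: Mapping[str, float],
    names: Mapping[str, str] | None = None,
) -> tuple[RankedList, list[str]]:
    """Order terms by PubMed-wide background count, ascending (rarer first).

    Terms missing from the background receive the background median;
    the list of imputed terms is returned alongside.
    """
    terms = list(terms)
    if not background:
        raise ValueError("background must be non-empty")
    median = float(np.median(list(background.values())))
    imputed = [t for t in terms if t not in background]
    for t in imputed:
        logger.warning("term %s missing from background; median %g imputed", t, median)
    label = (lambda t: names.get(t, t)) if names is not None else (lambda t: t)
    ordered = sorted(terms, key=lambda t: (background.get(t, median), label(t)))
    return RankedList("global_abundance", ordered), imputed


def normalize_ranks(
    lists: Sequence[RankedList], universe: Iterable[str]
) -> dict[str, np.ndarray]:
    """Per-term normalised rank vector, one component per list.

    A term at 1-based position i in a list of size N gets ``i / N``; a
    term absent from a list gets the conservative worst rank 1.0.
    """
    universe = list(universe)
    vectors = {t: np.ones(len(lists)) for t in universe}
    for j, rl in enumerate(lists):
        n = rl.size
        for i, term in enumerate(rl.ordering, 1):
            if term in vectors:
                vectors[term][j] = i / n
    return vectors


def rra_score(r: Sequence[float]) -> tuple[float, float, int]:
    """RRA beta-score of one normalised rank vector.

    Returns ``(rho, p_corrected, k_min)`` where ``rho = min_k beta_k``
    with ``beta_k = P(Binomial(n, r_(k)) >= k)`` over the ascending
    order statistics, ``p_corrected = min(1, rho * n)`` and ``k_min``
    the 1-based index attaining the minimum.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("rank vector must be a non-empty 1-d sequence")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("rank components must lie in (0, 1]")
    n = r.size
    r_sorted = np.sort(r)
    # exact upper binomial tail: P(X >= k) = sf(k - 1)
    betas = stats.binom.sf(np.arange(n), n, r_sorted)
    k_min = int(np.argmin(betas))
    rho = float(betas[k_min])
    return rho, float(min(1.0, rho * n)), k_min + 1


def rra_score_many(vectors: np.ndarray) -> np.ndarray:
    """Vectorised ``p_corrected`` for an (m, n) array of rank vectors."""
    v = np.sort(np.asarray(vectors, dtype=float), axis=1)
    m, n = v.shape
    betas = stats.binom.sf(np.arange(n)[None, :], n, v)
    return np.minimum(1.0, betas.min(axis=1) * n)


@dataclass
class PrioritisationResult:
    """Scored term table plus the resolution/imputation report."""

    table: pd.DataFrame
    unresolved_terms: list[str] = field(default_factory=list)
    imputed_terms: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def prioritise(
    corpus: Corpus, tree: MeshTree, background: Mapping[str, float]
) -> PrioritisationResult:
    """Rank the corpus's MeSH terms under the three criteria and fuse with RRA.

    Headings are resolved to descriptor uis (unresolvable headings are
    reported and excluded); the output table is sorted by corrected
    p-value ascending, ties by rho then descriptor name.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    raw_counts = mesh_term_counts(corpus)
    if not raw_counts:
        raise ValueError("corpus has no MeSH headings")

    counts: dict[str, int] = {}
    unresolved: list[str] = []
    for term, c in raw_counts.items():
        ui = tree.resolve(term)
        if ui is None:
            unresolved.append(term)
            logger.warning("MeSH heading %r not in vocabulary; excluded", term)
        else:
            counts[ui] = counts.get(ui, 0) + c
    if not counts:
        raise ValueError("no corpus heading could be resolved in the vocabulary")
    universe = sorted(counts)
    names = {u: tree.name(u) for u in universe}

    bg: dict[str, float] = {}
    for term, c in background.items():
        ui = tree.resolve(term)
        if ui is not None:
            bg[ui] = float(c)
    if not bg:
        raise ValueError("empty background")

    spec_list = rank_specificity(universe, tree)
    local_list = rank_local_abundance(counts, names)
    global_list, imputed = rank_global_abundance(universe, bg, names)
    lists = [spec_list, local_list, global_list]
    vectors = normalize_ranks(lists, universe)

    median_bg = float(np.median(list(bg.values())))
    rows = []
    for ui in universe:
        rho, p, k = rra_score(vectors[ui])
        rows.append(
            {
                "term": ui,
                "name": names[ui],
                "depth": tree.descriptor_depth(ui, "max"),
                "local_count": counts[ui],
                "global_count": bg.get(ui, median_bg),
                "r_specificity": vectors[ui][0],
                "r_local": vectors[ui][1],
                "r_global": vectors[ui][2],
                "rho": rho,
                "p_corrected": p,
                "k_min": k,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["p_corrected", "rho", "name"], kind="mergesort"
    ).reset_index(drop=True)
    return PrioritisationResult(table, unresolved, imputed)
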