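# Methods

## Scope and data model

`litmesh` treats a literature corpus as the bridge between two layers:
the biomedical annotation layer (MeSH headings on publication records)
and the molecular layer (GEO-style expression series linked to those
records). The corpus is an *ordered* list of records — the order is the
retrieval order of the upstream source (e.g. PubMed relevance ranking)
and is consumed as given, never recomputed. Live NCBI/GEO access is
isolated behind two small contracts (a `pmid -> record` fetcher and the
record-store path of the pipeline), so every computation here runs
offline and deterministically against fixture stores; a live adapter can
be slotted in without touching the analysis code.

## The MeSH forest

MeSH descriptors occupy one or more dot-separated tree positions
(`C04.557.470`), up to twelve levels deep in the real vocabulary. We
model the vocabulary as a position index (position → descriptor) plus a
descriptor table, with:

* **depth** = number of dot-fields of a position (`C04` → 1); a virtual
  root of depth 0 sits above the category codes so inter-category paths
  are defined;
* **LCA** of two descriptors = the deepest common-prefix ancestor over
  all placement pairs (virtual root when no pair shares a category;
  identity resolves to the deepest own placement);
* **shortest path** (in edges) = minimum over placement pairs of
  `(d_a − d_lca) + (d_b − d_lca)`;
* **descriptor specificity** = depth of the deepest placement.

Resolving multi-placement by optimising over placement pairs is the
standard ontology-similarity practice. One consequence worth noting:
the resulting descriptor-level distance is *not* a metric — a descriptor
placed in two distant categories can be near two terms that are far
from each other — so the triangle inequality is only guaranteed (and
only tested) on single-placement vocabularies. Qualifiers (subheadings)
and supplementary concept records are not modelled.

## Robust Rank Aggregation of three criteria

Corpus headings are ranked under three criteria: specificity (deepest
placement, descending), local abundance (number of distinct corpus
records annotated, descending) and global abundance (PubMed-wide
background count, ascending — globally rarer is better). The directions
implement a TF-IDF-like "specific, topic-enriched, globally rare"
notion; ties everywhere break on descriptor name ascending so output is
fully deterministic. Headings are aggregated as descriptor identifiers
(names are reported alongside); headings not in the vocabulary are
excluded and reported, and terms missing from the background receive
the background median (reported).

Each term's positions are normalised as r = position/N (terms absent
from a list get the conservative worst rank 1.0). With the ascending
order statistics r₍₁₎ ≤ … ≤ r₍ₙ₎, the beta-score is the exact upper
binomial tail βₖ = P(X ≥ k), X ~ Binomial(n, r₍ₖ₎); ρ = minₖ βₖ, and
the Bonferroni correction over the n order statistics gives
p = min(1, ρ·n). Tails are computed by `scipy.stats.binom.sf` (exact
summation; n = 3 lists here, so cost is nil) and are checked in the
tests against an independent integer-binomial summation oracle to
1e−12 and against a seeded 10⁵-draw uniform null for conservativeness.
The exact-p refinement of the original aggregation method beyond ρ·n is
deliberately out of scope.

## Semantic similarity

Six measures, all mapped to [0, 1]; `l` is the shortest path in edges,
`h` the LCA depth, `D` the vocabulary's maximum depth:

| measure | form | notes |
|---|---|---|
| shortest path | 1 − l/2D | floored at 0 |
| weighted link | 1 − L/L_max | edge into depth d weighs 2⁻ᵈ; L_max = 2·Σ₁..D 2⁻ᵈ |
| Wu–Palmer | 2h/(dₐ+d_b) | on the LCA-maximising placement pair; 0 at virtual root |
| Leacock–Chodorow | −ln((l+1)/2D)/ln 2D | node-counted path so identity is finite; clamped to [0, 1] |
| Li | e^(−αl)·tanh(βh) | α = 0.2, β = 0.6 defaults; identity = tanh(βh) < 1 by construction |
| Lord | IC(MICA)/IC_max | IC = −ln(count/total); 0 at virtual root |

The normalisation denominators (ln 2D, L_max, IC_max) are this
package's documented choices; they satisfy the unit-range requirement
but published variants of these measures differ in such constants, so
scores are comparable within `litmesh`, not across tools. For Lord, the
IC table holds *cumulative* occurrence counts (a node includes its
descendants); total mass is the sum over category-level descriptors and
IC_max is the largest IC attainable in the table, which makes the
measure invariant to rescaling all counts and gives self-similarity 1
exactly for minimal-count leaves (internal nodes self-score
IC(self)/IC_max < 1, the direct consequence of the formula).

Term sets are compared by the best-match average
`(Σ_a max_b s + Σ_b max_a s)/(|A|+|B|)`; the significance flag is
inclusive at 0.5, the conventional coin-flip threshold for "probability
that two term sets are similar".

## Expression series

A series is the pData/eData/tData triplet: per-sample phenotype
key/values, the probe × sample matrix (values taken as deposited — no
re-normalisation, no log detection), and the probe → gene dictionary.
The series-matrix reader accepts GEO's bang-prefixed export
(gzip-tolerant); non-numeric cells become missing values with a count
in the warnings. Probe collapse takes the cell-wise arithmetic mean of
a gene's probes (median available as an option; mean is the most common
collapse rule), excluding missing cells rather than imputing; unmapped
probes are dropped and counted. Sample stratification is lexicon-based
substring counting over the concatenated (sorted, hence field-order
invariant) phenotype text; the shipped lexicon covers the cancer family
(tumor/tumour/cancer/carcinoma/malignant/metasta) and the normal family
(normal/control/healthy/benign/adjacent); ties and zero hits map to
"unknown". This is a transparent rule-based stand-in for whatever
richer text-mining a deployment may plug in.

## Core analyses

* **PCA**: gene-mean-centred, unscaled, SVD-based; missing cells
  imputed to gene means (counted); component signs fixed by making each
  component's largest-magnitude loading positive, so scores are
  reproducible under sample reordering. Explained-variance fractions
  are relative to total variance and sum to 1 at full rank.
* **Variable genes / z-scores**: sample variance (ddof = 1) descending,
  name ties ascending; z-scores use the row sample-sd, zero-variance
  rows become zero with a warning.
* **Clustering**: agglomerative, Euclidean / complete linkage defaults;
  samples are name-sorted before linkage so the merge tree is
  invariant to input column order.
* **Gene network**: nodes are literature-associated genes with their
  supplied association scores (consumed, never recomputed); edges are
  exactly the interactome induced on the node set, weighted by the
  interactome score and annotated with the raw co-citation count
  (publications annotated with both endpoints). Co-citation is left as
  a count and emitted beside the interactome weight — no combined edge
  strength is fabricated because no principled denominator exists for a
  "rate" here.

## Synthetic bundle

The generator emulates the five inputs with one seed. Study conditions
(defaults): a 150-descriptor, depth-6 vocabulary over three categories
with ~10% multi-placement distractors; 60 records carrying 4 distractor
headings each; a 150-gene × 40-sample series (two balanced groups,
2 probes/gene plus 10 unmapped probes, Gaussian probe noise σ = 1);
a 200-edge interactome over 30 corpus genes plus 10 external genes.
Two signals are planted: (i) five headings that are the only
maximal-depth descriptors, annotate each record with probability 0.85
and receive background counts 20–80 against 10⁴–10⁶ for distractors —
the prioritisation should rank them top-5; (ii) ten genes whose probes
carry a 2·σ group mean-shift — they should populate the top-20 variable
genes after collapse (between-group variance ≈ 1 against residual
gene-level noise variance ≈ 0.5 after averaging two probes, a
comfortable margin at 40 samples). Sample titles/sources use
tumour/normal wording the default lexicon recognises.

What the generator does *not* emulate: real MeSH topology and
annotation correlations, platform-specific intensity distributions,
batch effects, unbalanced or mislabelled groups, and interactome degree
structure. Passing the recovery tests therefore demonstrates the
correctness of the computations under their stated assumptions, not
performance on real corpora.

## Numerical and engineering choices

Beta-scores by exact tail summation (no normal approximation). All
sort-based operations carry explicit name tie-breaks. TSV floats are
written with fixed formats so that identical inputs and seed yield
byte-identical run directories (verified in the tests by hashing two
runs); the run manifest records input digests, outputs, warnings and
the analyses performed per PMID:GSE pair, and contains no timestamps.
Problem sizes in the test-suite recovery experiments are the generator
defaults above; the Monte-Carlo null uses 10⁵ draws, large enough that
three binomial standard errors at α = 0.01 are below 0.001.

## Known limitations

Record order is trusted from the source ("best match" ranking is not
re-implemented); the similarity constants are not tuned to reproduce
any external benchmark; the stratification lexicon is deliberately
small; cancer-specific downstream analyses (tumour purity, molecular
subtyping) and interactive reports are out of scope — outputs are
static TSV/JSON/GraphML.
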