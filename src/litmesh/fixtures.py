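"""Synthetic, seeded fixture bundles emulating the pipeline's five inputs.

One call produces a mutually consistent bundle: a random MeSH-style
vocabulary TSV, literature records (JSON-lines) whose headings are drawn
from that vocabulary, a PubMed-wide background frequency table, a GEO
series-matrix file with probe -> gene platform annotation, per-record
gene annotations with association scores, and a scored interactome.

Two signals are planted so that recovery can be measured:

* **Prioritisation signal** — ``n_planted`` descriptors are the only
  maximal-depth headings in the vocabulary, annotate most records
  (inclusion probability ``planted_prob``), and receive small background
  counts, while distractor headings are shallower, sporadic and common
  PubMed-wide.  A correct three-criteria rank aggregation should place
  them at the top.
* **Expression signal** — two balanced sample groups (tumour vs adjacent
  normal, recognisable by the default stratification lexicon); a subset
  of genes carries a ``shift_sd`` x ``noise_sd`` group mean-shift on top
  of i.i.d. Gaussian probe noise, so those genes should surface among
  the most variable genes after probe collapsing.

All randomness flows from one integer seed; a bundle is byte-identical
on regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .literature import Corpus, PubRecord, write_corpus_jsonl

__all__ = ["FixtureBundle", "generate_fixtures"]


@dataclass
class FixtureBundle:
    """Paths of a generated bundle plus the planted ground truth."""

    out_dir: Path
    mesh_path: Path
    records_path: Path
    background_path: Path
    gene_scores_path: Path
    gene_annotations_path: Path
    interactome_path: Path
    series_matrix_path: Path
    platform_path: Path
    accession: str
    platform_accession: str
    planted_terms: list[str]        # descriptor uis
    shifted_genes: list[str]
    cancer_samples: list[str]
    normal_samples: list[str]
    seed: int


def _build_vocabulary(
    rng: np.random.Generator,
    n_descriptors: int,
    max_depth: int,
    n_planted: int,
    multi_placement_frac: float,
) -> tuple[list[tuple[str, str, list[str]]], list[str]]:
    """Return (ui, name, tree_numbers) rows and the planted uis.

    The planted descriptors terminate dedicated root-to-leaf chains and
    are the only descriptors at the maximal depth; distractors attach at
    depths up to ``max_depth - 1``.
    """
    roots = ["A01", "B01", "C01"]
    chain_cost = n_planted * (max_depth - 1)
    if max_depth < 2 or len(roots) + chain_cost > n_descriptors:
        raise ValueError("infeasible sizes: depth/planted chains exceed descriptor budget")

    positions: list[str] = list(roots)            # owners assigned below
    owner: dict[str, int] = {p: i for i, p in enumerate(roots)}
    n_nodes = len(roots)
    planted_idx: list[int] = []

    for j in range(n_planted):
        parent = "A01"
        for depth in range(2, max_depth + 1):
            pos = f"{parent}.{j + 1:03d}"
            positions.append(pos)
            owner[pos] = n_nodes
            if depth == max_depth:
                planted_idx.append(n_nodes)
            n_nodes += 1
            parent = pos

    child_counter: dict[str, int] = {}
    while n_nodes < n_descriptors:
        shallow = [p for p in positions if p.count(".") + 1 <= max_depth - 2]
        parent = shallow[int(rng.integers(len(shallow)))]
        child_counter[parent] = child_counter.get(parent, 100) + 1
        pos = f"{parent}.{child_counter[parent]:03d}"
        positions.append(pos)
        owner[pos] = n_nodes
        n_nodes += 1

    tree_numbers: dict[int, list[str]] = {}
    for pos, idx in owner.items():
        tree_numbers.setdefault(idx, []).append(pos)

    # secondary placements for a fraction of distractors
    distractors = [i for i in range(n_descriptors) if i not in set(planted_idx)]
    n_multi = int(multi_placement_frac * len(distractors))
    for idx in rng.choice(distractors, size=n_multi, replace=False):
        shallow = [p for p in positions if p.count(".") + 1 <= max_depth - 2]
        parent = shallow[int(rng.integers(len(shallow)))]
        child_counter[parent] = child_counter.get(parent, 100) + 1
        pos = f"{parent}.{child_counter[parent]:03d}"
        positions.append(pos)
        tree_numbers[int(idx)].append(pos)

    name_perm = rng.permutation(n_descriptors)
    rows = []
    for i in range(n_descriptors):
        rows.append(
            (f"D{i + 1:06d}", f"heading {name_perm[i] + 1:05d}", sorted(tree_numbers[i]))
        )
    planted_uis = [f"D{i + 1:06d}" for i in planted_idx]
    return rows, planted_uis


def generate_fixtures(
    seed: int,
    out_dir: str | Path,
    *,
    n_descriptors: int = 150,
    max_depth: int = 6,
    n_planted: int = 5,
    planted_prob: float = 0.85,
    multi_placement_frac: float = 0.1,
    n_records: int = 60,
    headings_per_record: int = 4,
    n_genes: int = 150,
    n_corpus_genes: int = 30,
    genes_per_record: tuple[int, int] = (2, 6),
    probes_per_gene: int = 2,
    n_unmapped_probes: int = 10,
    n_samples: int = 40,
    n_shifted_genes: int = 10,
    shift_sd: float = 2.0,
    noise_sd: float = 1.0,
    n_interactome_edges: int = 200,
    n_external_genes: int = 10,
) -> FixtureBundle:
    """Generate a consistent fixture bundle under ``out_dir``.

    Defaults define the standard study conditions: a 150-descriptor
    vocabulary of depth 6 with 5 planted terms, 60 records, a 150-gene /
    40-sample two-group series with a 2-sd mean shift on 10 genes, and a
    200-edge interactome.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if n_samples % 2:
        raise ValueError("n_samples must be even (two balanced groups)")
    if n_corpus_genes > n_genes:
        raise ValueError("n_corpus_genes cannot exceed n_genes")

    # -- vocabulary ------------------------------------------------------
    rows, planted_uis = _build_vocabulary(
        rng, n_descriptors, max_depth, n_planted, multi_placement_frac
    )
    mesh_path = out / "mesh_vocabulary.tsv"
    with open(mesh_path, "w", encoding="utf-8") as fh:
        for ui, name, tns in rows:
            fh.write(f"{ui}\t{name}\t{';'.join(tns)}\n")
    names = {ui: name for ui, name, _ in rows}
    distractor_uis = [ui for ui, _, _ in rows if ui not in set(planted_uis)]

    # -- background frequencies -----------------------------------------
    background_path = out / "background_counts.tsv"
    with open(background_path, "w", encoding="utf-8") as fh:
        fh.write("term\tcount\n")
        for ui, _, _ in rows:
            if ui in set(planted_uis):
                count = int(rng.integers(20, 80))
            else:
                count = int(rng.integers(10_000, 1_000_000))
            fh.write(f"{ui}\t{count}\n")

    # -- expression series ----------------------------------------------
    accession = "GSE900001"
    platform_accession = "GPL90001"
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    corpus_genes = genes[:n_corpus_genes]
    shifted_genes = sorted(
        rng.choice(genes, size=n_shifted_genes, replace=False).tolist()
    )
    samples = [f"GSM{900001 + i}" for i in range(n_samples)]
    half = n_samples // 2
    cancer_samples, normal_samples = samples[:half], samples[half:]

    baselines = rng.uniform(4.0, 12.0, size=n_genes)
    shift = shift_sd * noise_sd
    shifted_set = set(shifted_genes)
    probe_rows: list[tuple[str, str, np.ndarray]] = []  # (probe, gene, values)
    probe_no = 1000
    for gi, gene in enumerate(genes):
        for _ in range(probes_per_gene):
            values = baselines[gi] + rng.normal(0.0, noise_sd, size=n_samples)
            if gene in shifted_set:
                values[:half] += shift
            probe_rows.append((f"{probe_no}_at", gene, values))
            probe_no += 1
    for _ in range(n_unmapped_probes):
        values = rng.uniform(4.0, 12.0) + rng.normal(0.0, noise_sd, size=n_samples)
        probe_rows.append((f"{probe_no}_at", "", values))
        probe_no += 1

    series_matrix_path = out / f"{accession}_series_matrix.txt"
    with open(series_matrix_path, "w", encoding="utf-8") as fh:
        fh.write(f'!Series_geo_accession\t"{accession}"\n')
        titles = [f"breast tumor sample {i + 1}" for i in range(half)] + [
            f"adjacent normal tissue {i + 1}" for i in range(half)
        ]
        tissues = ["tissue: invasive breast carcinoma"] * half + [
            "tissue: adjacent normal breast"
        ] * half
        fh.write("!Sample_title\t" + "\t".join(f'"{t}"' for t in titles) + "\n")
        fh.write("!Sample_geo_accession\t" + "\t".join(f'"{s}"' for s in samples) + "\n")
        fh.write(
            "!Sample_source_name_ch1\t"
            + "\t".join(f'"{t}"' for t in tissues)
            + "\n"
        )
        fh.write(
            "!Sample_characteristics_ch1\t"
            + "\t".join(f'"platform: {platform_accession}"' for _ in samples)
            + "\n"
        )
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in samples]) + "\n")
        for probe, _, values in probe_rows:
            fh.write(
                "\t".join([f'"{probe}"'] + [f"{v:.4f}" for v in values]) + "\n"
            )
        fh.write("!series_matrix_table_end\n")

    platform_path = out / "platform_annotation.tsv"
    with open(platform_path, "w", encoding="utf-8") as fh:
        fh.write("ID\tGENE_SYMBOL\n")
        for probe, gene, _ in probe_rows:
            fh.write(f"{probe}\t{gene}\n")

    # -- literature records ---------------------------------------------
    records: list[PubRecord] = []
    ann: dict[str, list[str]] = {}
    journals = ["J Synth Biomed", "Fixture Med", "Ann Generated Res"]
    for i in range(n_records):
        pmid = str(90_000_001 + i)
        headings = [names[ui] for ui in planted_uis if rng.random() < planted_prob]
        extra = rng.choice(distractor_uis, size=headings_per_record, replace=False)
        headings.extend(names[ui] for ui in extra)
        n_g = int(rng.integers(genes_per_record[0], genes_per_record[1] + 1))
        rec_genes = sorted(rng.choice(corpus_genes, size=n_g, replace=False).tolist())
        ann[pmid] = rec_genes
        linked = i < 3
        records.append(
            PubRecord(
                pmid=pmid,
                title=f"Synthetic study {i + 1} of planted-topic expression",
                authors=[f"Author{i + 1:03d} A", "Fixture B"],
                journal=journals[i % len(journals)],
                pub_date=f"{2015 + int(rng.integers(0, 5))}-"
                f"{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
                mesh_headings=headings,
                gse_codes=[accession] if linked else [],
                platforms=[platform_accession] if linked else [],
                ftp_links=(
                    [f"ftp://ftp.ncbi.nlm.nih.gov/geo/series/{accession}/"]
                    if linked
                    else []
                ),
            )
        )
    records_path = out / "records.jsonl"
    write_corpus_jsonl(Corpus(records=records, query="synthetic planted topic"), records_path)

    gene_annotations_path = out / "gene_annotations.tsv"
    with open(gene_annotations_path, "w", encoding="utf-8") as fh:
        fh.write("pmid\tgenes\n")
        for pmid in sorted(ann):
            fh.write(f"{pmid}\t{';'.join(ann[pmid])}\n")

    citation_counts: dict[str, int] = {}
    for rec_genes in ann.values():
        for g in rec_genes:
            citation_counts[g] = citation_counts.get(g, 0) + 1
    gene_scores_path = out / "gene_scores.tsv"
    with open(gene_scores_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for g in sorted(citation_counts):
            fh.write(f"{g}\t{citation_counts[g]}\n")

    # -- interactome -----------------------------------------------------
    pool = corpus_genes + [f"EXT{i + 1:04d}" for i in range(n_external_genes)]
    max_pairs = len(pool) * (len(pool) - 1) // 2
    n_edges = min(n_interactome_edges, max_pairs)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str, float]] = []
    while len(edges) < n_edges:
        a, b = rng.choice(pool, size=2, replace=False)
        pair = tuple(sorted((str(a), str(b))))
        if pair in seen:
            continue
        seen.add(pair)
        edges.append((pair[0], pair[1], round(float(rng.uniform(0.05, 1.0)), 3)))
    interactome_path = out / "interactome.tsv"
    with open(interactome_path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, s in sorted(edges):
            fh.write(f"{a}\t{b}\t{s:g}\n")

    bundle = FixtureBundle(
        out_dir=out,
        mesh_path=mesh_path,
        records_path=records_path,
        background_path=background_path,
        gene_scores_path=gene_scores_path,
        gene_annotations_path=gene_annotations_path,
        interactome_path=interactome_path,
        series_matrix_path=series_matrix_path,
        platform_path=platform_path,
        accession=accession,
        platform_accession=platform_accession,
        planted_terms=list(planted_uis),
        shifted_genes=shifted_genes,
        cancer_samples=cancer_samples,
        normal_samples=normal_samples,
        seed=seed,
    )
    with open(out / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": seed,
                "accession": accession,
                "platform": platform_accession,
                "planted_terms": bundle.planted_terms,
                "shifted_genes": bundle.shifted_genes,
                "cancer_samples": bundle.cancer_samples,
                "normal_samples": bundle.normal_samples,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return bundle
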