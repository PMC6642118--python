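"""Expression series as the pData / eData / tData triplet.

One GEO-style series is held as three tables mirroring sample-level
granularity: ``pdata`` — per-sample phenotype attributes (free-text
key/value, one row per sample); ``edata`` — the probe x sample numeric
expression matrix, in platform-native units, taken as deposited; and
``tdata`` — the platform's probe -> gene-symbol dictionary used to
collapse probe-level rows to gene level.

The series-matrix reader accepts GEO's tab-separated export: bang-
prefixed ``!Sample_*`` metadata lines followed by the expression table
between ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
markers (gzip-tolerant).  Sample stratification into biological groups —
in particular cancer versus normal/control — is lexicon-driven keyword
matching over the concatenated phenotype values.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeoSeries",
    "SampleGroups",
    "DEFAULT_LEXICON",
    "parse_series_matrix",
    "read_platform_table",
    "write_series_matrix",
    "collapse_probes",
    "stratify_samples",
]

Source = Union[str, Path, TextIO]

#: Default stratification lexicon: group label -> substrings (lower case).
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "cancer": ("tumor", "tumour", "cancer", "carcinoma", "malignant", "metasta"),
    "normal": ("normal", "control", "healthy", "benign", "adjacent"),
}


@dataclass
class GeoSeries:
    """One expression series: phenotype, expression and platform tables."""

    accession: str
    pdata: pd.DataFrame
    edata: pd.DataFrame
    tdata: pd.DataFrame | None = None
    n_missing: int = 0

    def __post_init__(self) -> None:
        if not set(self.edata.columns) <= set(self.pdata.index):
            raise ValueError("edata columns must be a subset of pdata samples")
        if self.edata.index.has_duplicates:
            raise ValueError("duplicate probe identifiers in edata")
        if self.tdata is not None and self.tdata.index.has_duplicates:
            raise ValueError("duplicate probe identifiers in tdata")

    @property
    def samples(self) -> list[str]:
        return list(self.edata.columns)


@dataclass
class SampleGroups:
    """Per-sample biological group and cancer/normal flag."""

    group: dict[str, str]
    cancer_flag: dict[str, str]  # cancer | normal | unknown

    def to_frame(self) -> pd.DataFrame:
        samples = list(self.group)
        return pd.DataFrame(
            {
                "sample": samples,
                "group": [self.group[s] for s in samples],
                "cancer_flag": [self.cancer_flag[s] for s in samples],
            }
        )


def _open_text(source: Source):
    if isinstance(source, (str, Path)):
        p = str(source)
        if p.endswith(".gz"):
            return gzip.open(p, "rt", encoding="utf-8"), True
        return open(p, "r", encoding="utf-8"), True
    return source, False


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def parse_series_matrix(
    source: Source, platform: pd.DataFrame | None = None
) -> GeoSeries:
    """Parse a GEO series-matrix stream into a :class:`GeoSeries`.

    ``!Sample_<key>`` lines become pdata columns (repeated keys are
    suffixed ``.1``, ``.2``, ...); the block between the table markers
    becomes edata.  Non-numeric expression cells (e.g. ``null``) are
    recorded as missing with a warning.  *platform* optionally supplies
    the probe -> gene table when it is not distributed with the series.
    """
    stream, close = _open_text(source)
    try:
        meta: dict[str, list[str]] = {}
        meta_order: list[str] = []
        accession = ""
        table_lines: list[str] = []
        in_table = False
        saw_begin = False
        for raw in stream:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
                continue
            if line.startswith("!Series_geo_accession"):
                parts = line.split("\t")
                if len(parts) > 1:
                    accession = _unquote(parts[1])
            elif line.startswith("!Sample_"):
                key, *values = line.split("\t")
                key = key[len("!Sample_"):]
                n = sum(1 for k in meta_order if k == key or k.startswith(key + "."))
                if n:
                    key = f"{key}.{n}"
                meta[key] = [_unquote(v) for v in values]
                meta_order.append(key)
        if not saw_begin:
            raise ValueError("missing !series_matrix_table_begin marker")
        if not table_lines:
            raise ValueError("empty series-matrix table")

        header = [_unquote(c) for c in table_lines[0].split("\t")]
        samples = header[1:]
        probes, rows = [], []
        for line in table_lines[1:]:
            cells = line.split("\t")
            probes.append(_unquote(cells[0]))
            rows.append([_unquote(c) for c in cells[1:]])
        raw_df = pd.DataFrame(rows, index=probes, columns=samples)
        edata = raw_df.apply(pd.to_numeric, errors="coerce")
        n_missing = int(edata.isna().sum().sum())
        if n_missing:
            logger.warning("%d non-numeric expression cells recorded as missing", n_missing)
        edata.index.name = "probe"

        if meta:
            pdata = pd.DataFrame(meta)
            if "geo_accession" in pdata.columns and list(pdata["geo_accession"]) == samples:
                pdata.index = pd.Index(samples, name="sample")
            elif len(pdata) == len(samples):
                pdata.index = pd.Index(samples, name="sample")
            else:
                raise ValueError("sample metadata width does not match the table")
        else:
            pdata = pd.DataFrame(index=pd.Index(samples, name="sample"))
        return GeoSeries(
            accession=accession or "GSE0",
            pdata=pdata,
            edata=edata,
            tdata=platform,
            n_missing=n_missing,
        )
    finally:
        if close:
            stream.close()


def read_platform_table(source: Source) -> pd.DataFrame:
    """Read a probe -> gene annotation TSV (columns: probe id, gene symbol)."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    probe_col, gene_col = df.columns[0], df.columns[1]
    out = df[[probe_col, gene_col]].rename(columns={probe_col: "probe", gene_col: "gene"})
    out = out.set_index("probe")
    out["gene"] = out["gene"].replace("", np.nan)
    return out


def write_series_matrix(series: GeoSeries, path: Union[str, Path]) -> None:
    """Write a series back in the series-matrix dialect (round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f'!Series_geo_accession\t"{series.accession}"\n')
        for col in series.pdata.columns:
            base = col.rsplit(".", 1)[0] if col.rsplit(".", 1)[-1].isdigit() else col
            values = "\t".join(f'"{v}"' for v in series.pdata[col])
            fh.write(f"!Sample_{base}\t{values}\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in series.edata.columns]) + "\n")
        for probe, row in series.edata.iterrows():
            cells = ["null" if pd.isna(v) else repr(float(v)) for v in row]
            fh.write("\t".join([f'"{probe}"'] + cells) + "\n")
        fh.write("!series_matrix_table_end\n")


def collapse_probes(
    edata: pd.DataFrame,
    tdata: pd.DataFrame,
    stat: str = "mean",
) -> tuple[pd.DataFrame, int]:
    """Collapse the probe x sample matrix to gene level.

    Each gene row is the per-cell *stat* (``mean`` or ``median``) of its
    probes' rows, missing values excluded cell-wise.  Probes without a
    gene mapping are dropped; their count is returned alongside.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown collapse statistic {stat!r}")
    genes = tdata["gene"] if "gene" in tdata.columns else tdata.iloc[:, 0]
    mapping = genes.dropna()
    mapped = edata.index.intersection(mapping.index)
    dropped = len(edata.index) - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no edata probe maps to a gene")
    grouped = edata.loc[mapped].groupby(mapping.loc[mapped])
    out = grouped.mean() if stat == "mean" else grouped.median()
    out.index.name = "gene"
    return out.sort_index(), dropped


def stratify_samples(
    pdata: pd.DataFrame,
    lexicon: Mapping[str, Sequence[str]] | None = None,
    cancer_labels: Sequence[str] = ("cancer",),
    normal_labels: Sequence[str] = ("normal",),
) -> SampleGroups:
    """Assign each sample to the lexicon group with most keyword hits.

    Keyword occurrences are counted case-insensitively over the
    concatenation of the sample's phenotype values (order-invariant).
    Ties and zero hits yield ``unknown``; the cancer/normal flag follows
    the family (*cancer_labels* / *normal_labels*) of the winning group.
    """
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    lex = {k: tuple(v) for k, v in lexicon.items()}
    if not lex:
        raise ValueError("lexicon must be non-empty")
    group: dict[str, str] = {}
    flag: dict[str, str] = {}
    for sample, row in pdata.iterrows():
        text = " | ".join(sorted(str(v).lower() for v in row.values))
        hits = {label: sum(text.count(kw.lower()) for kw in kws) for label, kws in lex.items()}
        best = max(hits.values(), default=0)
        winners = [label for label, h in hits.items() if h == best and h > 0]
        label = winners[0] if len(winners) == 1 else "unknown"
        group[str(sample)] = label
        if label in cancer_labels:
            flag[str(sample)] = "cancer"
        elif label in normal_labels:
            flag[str(sample)] = "normal"
        else:
            flag[str(sample)] = "unknown"
    return SampleGroups(group=group, cancer_flag=flag)
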