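"""MeSH vocabulary model and structural queries.

The Medical Subject Headings thesaurus is a forest of 16 categories in
which descriptors are arranged from general to specific.  A descriptor
carries one or more *tree numbers* — dot-separated position codes such as
``C04.557.470`` — and may therefore occupy several places in the forest at
once.  All structural queries here (depth, lowest common ancestor,
shortest path) resolve that multi-placement by optimising over all
placement pairs.

Depth convention: the depth of a position is its number of dot-separated
fields (``C04`` -> 1).  A virtual root of depth 0 sits above all
category-level codes, so paths between categories are always defined.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

__all__ = [
    "MeshDescriptor",
    "MeshTree",
    "parse_mesh",
    "tree_number_depth",
]

TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{3})*$")

Source = Union[str, Path, TextIO]


def tree_number_depth(position: str) -> int:
    """Depth of a tree-number code = number of dot-separated fields."""
    return position.count(".") + 1


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH descriptor: identifier, preferred heading and placements."""

    ui: str
    name: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ui:
            raise ValueError("descriptor ui must be non-empty")
        if not self.tree_numbers:
            raise ValueError(f"descriptor {self.ui!r} has no tree numbers")
        for tn in self.tree_numbers:
            if not TREE_NUMBER_RE.match(tn):
                raise ValueError(
                    f"malformed tree number {tn!r} on descriptor {self.ui!r}"
                )


class MeshTree:
    """The vocabulary as a multi-placement hierarchy.

    Parameters
    ----------
    descriptors:
        Iterable of :class:`MeshDescriptor`.  Every tree number's parent
        prefix (all but the last dot-field) must itself be a tree number
        of some descriptor; category-level codes have the virtual root as
        parent.
    """

    def __init__(self, descriptors: Iterable[MeshDescriptor]) -> None:
        self.descriptors: dict[str, MeshDescriptor] = {}
        self.position_index: dict[str, str] = {}
        for d in descriptors:
            if d.ui in self.descriptors:
                raise ValueError(f"duplicate descriptor ui {d.ui!r}")
            self.descriptors[d.ui] = d
            for tn in d.tree_numbers:
                if tn in self.position_index:
                    raise ValueError(
                        f"tree number {tn!r} assigned to both "
                        f"{self.position_index[tn]!r} and {d.ui!r}"
                    )
                self.position_index[tn] = d.ui
        if not self.descriptors:
            raise ValueError("empty vocabulary")
        for tn in self.position_index:
            if "." in tn:
                parent = tn.rsplit(".", 1)[0]
                if parent not in self.position_index:
                    raise ValueError(
                        f"orphan tree number {tn!r}: parent {parent!r} absent"
                    )
        self.max_depth = max(tree_number_depth(tn) for tn in self.position_index)
        self._name_index = {d.name: d.ui for d in self.descriptors.values()}

    # -- lookups ---------------------------------------------------------

    def __contains__(self, ui: str) -> bool:
        return ui in self.descriptors

    def __len__(self) -> int:
        return len(self.descriptors)

    def resolve(self, term: str) -> str | None:
        """Map a descriptor ui or preferred name to its ui; None if unknown."""
        if term in self.descriptors:
            return term
        return self._name_index.get(term)

    def name(self, ui: str) -> str:
        return self._get(ui).name

    def _get(self, ui: str) -> MeshDescriptor:
        try:
            return self.descriptors[ui]
        except KeyError:
            raise KeyError(f"unknown descriptor {ui!r}") from None

    def depth(self, position: str) -> int:
        """Depth of an indexed position (category level = 1)."""
        if position not in self.position_index:
            raise KeyError(f"unknown tree position {position!r}")
        return tree_number_depth(position)

    def descriptor_depth(self, ui: str, mode: str = "max") -> int:
        """Deepest (``max``) or shallowest (``min``) placement depth of *ui*."""
        d = self._get(ui)
        depths = [tree_number_depth(tn) for tn in d.tree_numbers]
        if mode == "max":
            return max(depths)
        if mode == "min":
            return min(depths)
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")

    # -- structural queries ----------------------------------------------

    @staticmethod
    def _common_prefix(pos_a: str, pos_b: str) -> str | None:
        """Deepest common-prefix ancestor of two positions, None = virtual root."""
        fa, fb = pos_a.split("."), pos_b.split(".")
        n = 0
        for x, y in zip(fa, fb):
            if x != y:
                break
            n += 1
        if n == 0:
            return None
        return ".".join(fa[:n])

    def lca(self, ui_a: str, ui_b: str) -> tuple[str | None, int]:
        """Lowest common ancestor over all placement pairs.

        Returns ``(position, depth)``; the position is ``None`` (virtual
        root, depth 0) when no placement pair shares a category.
        ``lca(a, a)`` is *a*'s deepest placement.
        """
        pos, depth, _, _ = self.lca_detail(ui_a, ui_b)
        return pos, depth

    def lca_detail(self, ui_a: str, ui_b: str) -> tuple[str | None, int, int, int]:
        """LCA plus the placement depths of the pair that realises it.

        Among placement pairs achieving the maximal LCA depth, the pair
        with the smallest combined depth is chosen (ties broken
        lexicographically for determinism).
        """
        da, db = self._get(ui_a), self._get(ui_b)
        best: tuple[int, int, str, str, str | None] | None = None
        for pa in da.tree_numbers:
            for pb in db.tree_numbers:
                if ui_a == ui_b:
                    anc: str | None = pa if pa == pb else self._common_prefix(pa, pb)
                else:
                    anc = self._common_prefix(pa, pb)
                d = tree_number_depth(anc) if anc is not None else 0
                key = (-d, tree_number_depth(pa) + tree_number_depth(pb), pa, pb)
                if best is None or key < (-best[0], best[1], best[2], best[3]):
                    best = (d, tree_number_depth(pa) + tree_number_depth(pb), pa, pb, anc)
        assert best is not None
        d, _, pa, pb, anc = best
        return anc, d, tree_number_depth(pa), tree_number_depth(pb)

    def shortest_path_edges(self, ui_a: str, ui_b: str) -> int:
        """Minimum edge count between any placements of the two descriptors.

        Paths run through common-prefix ancestors, or through the virtual
        root when placements share no category.
        """
        da, db = self._get(ui_a), self._get(ui_b)
        if ui_a == ui_b:
            return 0
        best = None
        for pa in da.tree_numbers:
            for pb in db.tree_numbers:
                anc = self._common_prefix(pa, pb)
                d = tree_number_depth(anc) if anc is not None else 0
                length = (tree_number_depth(pa) - d) + (tree_number_depth(pb) - d)
                if best is None or length < best:
                    best = length
        assert best is not None
        return best

    def ancestor_uis(self, ui: str) -> set[str]:
        """All descriptor uis on root-ward paths from *ui*, including itself."""
        out: set[str] = set()
        for tn in self._get(ui).tree_numbers:
            fields = tn.split(".")
            for i in range(1, len(fields) + 1):
                anc_ui = self.position_index.get(".".join(fields[:i]))
                if anc_ui is not None:
                    out.add(anc_ui)
        return out


# -- parsing ------------------------------------------------------------


def _as_stream(source: Source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _iter_ascii_records(stream: TextIO) -> Iterator[dict[str, list[str]]]:
    record: dict[str, list[str]] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "*NEWRECORD" or not line.strip():
            if record:
                yield record
                record = {}
            continue
        if " = " in line:
            key, value = line.split(" = ", 1)
            record.setdefault(key.strip(), []).append(value.strip())
    if record:
        yield record


def parse_mesh(source: Source, dialect: str = "tsv") -> MeshTree:
    """Parse a vocabulary stream into a :class:`MeshTree`.

    Dialects
    --------
    ``tsv``
        Three tab-separated columns: ui, preferred name, semicolon-joined
        tree numbers.  Lines starting with ``#`` are skipped.
    ``mesh-ascii``
        NLM descriptor ASCII records (``*NEWRECORD`` blocks with
        ``MH =``, ``MN =``, ``UI =`` lines).
    """
    stream = _as_stream(source)
    close = isinstance(source, (str, Path))
    try:
        descriptors: list[MeshDescriptor] = []
        if dialect == "tsv":
            for lineno, raw in enumerate(stream, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"line {lineno}: expected 3 tab-separated columns"
                    )
                ui, name, tns = (p.strip() for p in parts)
                numbers = tuple(t.strip() for t in tns.split(";") if t.strip())
                descriptors.append(MeshDescriptor(ui, name, numbers))
        elif dialect == "mesh-ascii":
            for rec in _iter_ascii_records(stream):
                if "UI" not in rec or "MH" not in rec:
                    raise ValueError(f"record missing UI or MH line: {rec}")
                descriptors.append(
                    MeshDescriptor(
                        rec["UI"][0], rec["MH"][0], tuple(rec.get("MN", []))
                    )
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        if not descriptors:
            raise ValueError("empty vocabulary")
        return MeshTree(descriptors)
    finally:
        if close:
            stream.close()


def write_mesh_tsv(tree: MeshTree, path: Union[str, Path]) -> None:
    """Write the vocabulary in the three-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for ui in sorted(tree.descriptors):
            d = tree.descriptors[ui]
            fh.write(f"{d.ui}\t{d.name}\t{';'.join(d.tree_numbers)}\n")
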