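"""Readers and writers for gene sets, networks, universes and result tables.

All identifiers are plain strings in a single caller-declared namespace
(gene symbols for synthetic data, stringified Entrez IDs for the packaged
fixtures); no cross-namespace mapping is attempted.

The numeric-cell parser understands the decimal-comma dialect used by the
published enrichment tables ("3,62292E-10"); everything this package writes
uses decimal points.
"""
from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneSet",
    "GeneSetCollection",
    "PPINetwork",
    "Universe",
    "parse_decimal",
    "read_edge_list",
    "read_gmt",
    "read_mitab_min",
    "read_universe",
    "write_edge_list",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
    "write_gmt",
    "write_universe",
]

RESULT_COLUMNS = [
    "term_id", "name", "source", "obs", "odds_ratio",
    "p_or_fdr", "corrected", "significant",
]


class FormatError(ValueError):
    """A stream violated its declared format; carries the line number."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set members must be non-empty")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets sharing one source label (GO, KEGG, Reactome, ...)."""

    source: str
    sets: Mapping[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class Universe:
    """The tested gene space enrichment is computed within."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("universe must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in self.genes


class PPINetwork:
    """Undirected protein-protein interaction network.

    Stores at most one edge per unordered pair; self-loops are retained but
    kept apart from proper edges (they never contribute neighbors).
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.nodes: frozenset[str] = frozenset(nodes)
        proper: set[tuple[str, str]] = set()
        loops: set[str] = set()
        adjacency: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if u == v:
                loops.add(u)
                continue
            a, b = (u, v) if u <= v else (v, u)
            proper.add((a, b))
            adjacency[a].add(b)
            adjacency[b].add(a)
        self.edges: frozenset[tuple[str, str]] = frozenset(proper)
        self.self_loops: frozenset[str] = frozenset(loops)
        self._adjacency = adjacency

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adjacency[node])

    def degree(self, node: str) -> int:
        return len(self._adjacency[node])

    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.self_loops == other.self_loops
        )

    def with_edges(self, extra: Iterable[tuple[str, str]]) -> "PPINetwork":
        """A copy with additional edges (nodes unchanged)."""
        return PPINetwork(
            self.nodes,
            list(self.edges) + [(u, u) for u in self.self_loops] + list(extra),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        g.add_edges_from((u, u) for u in self.self_loops)
        return g

    @classmethod
    def from_networkx(cls, graph) -> "PPINetwork":
        return cls(graph.nodes(), graph.edges())


def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_gmt(source, source_label: str = "") -> GeneSetCollection:
    """Read a GMT stream or path: term, description, then members.

    Members are deduplicated; the description field becomes the set name.
    Lines with fewer than three fields raise :class:`FormatError` with the
    line number.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"GMT line {lineno}: expected >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        term_id, name, *members = fields
        members = [m for m in members if m]
        if term_id in sets:
            raise FormatError(f"GMT line {lineno}: duplicate term {term_id!r}")
        sets[term_id] = GeneSet(name=name, members=frozenset(members))
    return GeneSetCollection(source=source_label, sets=sets)


def write_gmt(collection: GeneSetCollection, stream: IO[str]) -> None:
    for term_id, gs in collection.sets.items():
        stream.write(
            "\t".join([term_id, gs.name, *sorted(gs.members)]) + "\n"
        )


def read_edge_list(source) -> PPINetwork:
    """Read a two-column whitespace/tab edge list; ``#`` lines are comments.

    "A B" and "B A" collapse to one undirected edge; "A A" is kept as a
    flagged self-loop.
    """
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(
                f"edge list line {lineno}: expected 2 fields, got {len(fields)}"
            )
        u, v = fields
        nodes.update((u, v))
        edges.append((u, v))
    return PPINetwork(nodes, edges)


def write_edge_list(network: PPINetwork, stream: IO[str]) -> None:
    for u in sorted(network.self_loops):
        stream.write(f"{u}\t{u}\n")
    for u, v in sorted(network.edges):
        stream.write(f"{u}\t{v}\n")
    # isolated nodes round-trip as degenerate comment-free singletons is not
    # possible in a pure edge list; callers needing them write a universe too


def read_mitab_min(source) -> PPINetwork:
    """Minimal PSI-MITAB 2.5 reader: columns 1-2 only, topology only.

    Each identifier cell holds pipe-joined ``db:accession`` entries; the
    first parseable accession is used.  Header lines starting with ``#`` are
    skipped; rows whose identifiers cannot be parsed are skipped with a
    logged warning.
    """
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError(
                f"MITAB line {lineno}: expected >=2 columns, got {len(cols)}"
            )
        ids = []
        for cell in cols[:2]:
            acc = None
            for entry in cell.split("|"):
                entry = entry.strip()
                if ":" in entry:
                    db, _, rest = entry.partition(":")
                    rest = rest.strip().strip('"')
                    if db and rest:
                        acc = rest
                        break
            ids.append(acc)
        if ids[0] is None or ids[1] is None:
            logger.warning("MITAB line %d: unparseable identifier, skipped", lineno)
            continue
        nodes.update(ids)
        edges.append((ids[0], ids[1]))
    return PPINetwork(nodes, edges)


def read_universe(source) -> Universe:
    """Read a one-column list of gene identifiers (``#`` lines skipped)."""
    genes: set[str] = set()
    for line in _as_lines(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line.split()[0])
    return Universe(frozenset(genes))


def write_universe(universe: Universe, stream: IO[str]) -> None:
    for g in sorted(universe.genes):
        stream.write(g + "\n")


_DECIMAL_RE = re.compile(
    r"^[+-]?(\d+)([.,]\d+)?([eE][+-]?\d+)?$"
)


def parse_decimal(text: str) -> float:
    """Parse a numeric cell that may use a decimal comma.

    Accepts integer, decimal-point, decimal-comma and scientific notation
    with either mantissa style ("102,352" → 102.352, "3,62292E-10" →
    3.62292e-10).  Thousands separators are not supported.
    """
    cell = text.strip()
    if not _DECIMAL_RE.match(cell):
        raise ValueError(f"not a numeric cell: {text!r}")
    return float(cell.replace(",", "."))


def write_enrichment_tsv(rows: Sequence, stream: IO[str]) -> None:
    """Write enrichment rows as a decimal-point TSV.

    Accepts any sequence of objects (dataclasses or mappings) exposing the
    unified result fields; missing fields are written empty.  Floats are
    written with ``repr`` so a read-back reproduces them exactly.
    """
    stream.write("\t".join(RESULT_COLUMNS) + "\n")
    for row in rows:
        get = row.get if isinstance(row, Mapping) else lambda k, d=None: getattr(row, k, d)
        out = []
        for col in RESULT_COLUMNS:
            val = get(col)
            if val is None:
                out.append("")
            elif isinstance(val, bool):
                out.append("true" if val else "false")
            elif isinstance(val, float):
                out.append(repr(val))
            else:
                out.append(str(val))
        stream.write("\t".join(out) + "\n")


def read_enrichment_tsv(source) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_enrichment_tsv`."""
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(
            _stdio.StringIO(source.read()), sep="\t", dtype=str,
            keep_default_na=False,
        )
    for col in ("obs",):
        if col in df:
            df[col] = df[col].map(lambda s: int(s) if s else None)
    for col in ("odds_ratio", "p_or_fdr", "corrected"):
        if col in df:
            df[col] = df[col].map(lambda s: float(s) if s else None)
    if "significant" in df:
        df["significant"] = df["significant"].map(
            lambda s: {"true": True, "false": False}.get(s, None)
        )
    return df
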