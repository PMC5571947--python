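"""Citation-corpus data model, I/O, and diffusion-cascade extraction.

A citation corpus is a directed graph whose nodes are articles and whose
edges point from the citing article to the cited one.  Read in that
direction, a chain of citations is a chain of adoption: every article that
cites a seed article, directly or through intermediaries, belongs to the
seed's diffusion cascade.  Cascades are therefore the *reverse-reachability*
set of a seed — all nodes with a directed citation path terminating at it —
together with the citation edges induced among the members.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleRecord",
    "CitationGraph",
    "Cascade",
    "parse_pub_date",
    "load_corpus",
    "extract_cascade",
    "all_cascades",
    "export_graph",
    "load_edge_list",
]

_YEAR_RE = re.compile(r"^(\d{4})$")
_YEAR_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")
_FULL_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")


def parse_pub_date(text: str) -> _dt.date:
    """Parse an ISO-8601 publication date of day, month, or year precision.

    Bibliographic records often lack day precision.  The deterministic
    convention used throughout the package is: a month-only date resolves to
    day 15 of that month and a year-only date to July 1 of that year.

    Raises
    ------
    ValueError
        If ``text`` is not a valid ISO date at any of the three precisions.
    """
    text = text.strip()
    if m := _FULL_RE.match(text):
        return _dt.date(int(m[1]), int(m[2]), int(m[3]))
    if m := _YEAR_MONTH_RE.match(text):
        return _dt.date(int(m[1]), int(m[2]), 15)
    if m := _YEAR_RE.match(text):
        return _dt.date(int(m[1]), 7, 1)
    raise ValueError(f"unparseable publication date: {text!r}")


@dataclass(frozen=True)
class ArticleRecord:
    """One publication in the corpus.

    ``evidence_category`` is the article's ordinal position (1..8) in the
    innovation funnel, from the earliest pre-clinical stage (1) to the final
    implementation stage (8); it is an input, never inferred from text.
    """

    article_id: str
    pub_date: _dt.date
    specialty: str | None = None
    evidence_category: int | None = None

    def __post_init__(self) -> None:
        if self.evidence_category is not None and not (
            1 <= int(self.evidence_category) <= 8
        ):
            raise ValueError(
                f"article {self.article_id!r}: evidence_category must be in "
                f"[1, 8], got {self.evidence_category}"
            )


class CitationGraph:
    """Directed citation graph; edge (i, j) means *i cites j*.

    Wraps a :class:`networkx.DiGraph` whose nodes are article ids and keeps
    the :class:`ArticleRecord` objects in ``records``.  Invariants enforced
    at construction: unique article ids, no self-loops, no duplicate edges,
    every edge endpoint known.
    """

    def __init__(
        self,
        records: Iterable[ArticleRecord],
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.records: dict[str, ArticleRecord] = {}
        for rec in records:
            if rec.article_id in self.records:
                raise ValueError(f"duplicate article_id: {rec.article_id!r}")
            self.records[rec.article_id] = rec
        g = nx.DiGraph()
        g.add_nodes_from(self.records)
        n_dup = n_self = 0
        for citing, cited in edges:
            for endpoint in (citing, cited):
                if endpoint not in self.records:
                    raise ValueError(
                        f"edge ({citing!r}, {cited!r}) references unknown "
                        f"article_id {endpoint!r}"
                    )
            if citing == cited:
                n_self += 1
                continue
            if g.has_edge(citing, cited):
                n_dup += 1
                continue
            g.add_edge(citing, cited)
        if n_dup:
            logger.warning("collapsed %d duplicate citation edge(s)", n_dup)
        if n_self:
            logger.warning("dropped %d self-citation edge(s)", n_self)
        if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
            # Mutually citing simultaneous publications are tolerated:
            # reachability and shortest paths remain well-defined.
            logger.info("citation graph contains directed cycles")
        self.graph = g

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self.graph.edges())

    def citation_count(self, article_id: str) -> int:
        """Within-corpus citations received by ``article_id``."""
        return self.graph.in_degree(article_id)

    def __contains__(self, article_id: str) -> bool:
        return article_id in self.records

    def __repr__(self) -> str:  # pragma: no cover
        return f"CitationGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class Cascade:
    """A seed article plus every direct or indirect citer, with induced edges.

    Downstream metrics operate exclusively on the induced edge set: the
    cascade is a set of articles and the only coherent path structure is the
    one among its members.
    """

    seed_id: str
    member_ids: frozenset[str]
    edges: frozenset[tuple[str, str]]
    records: Mapping[str, ArticleRecord] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed_id not in self.member_ids:
            raise ValueError("seed_id must be a cascade member")

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def subgraph(self) -> nx.DiGraph:
        """Induced digraph over the members (edge = citing → cited)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.member_ids)
        g.add_edges_from(self.edges)
        return g


def _read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a CSV/TSV file with a header row, sniffing the delimiter."""
    path = Path(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty table")
        return [dict(row) for row in reader]


def load_corpus(node_table: str | Path, edge_table: str | Path) -> CitationGraph:
    """Load a citation corpus from delimited node and edge tables.

    The node table requires columns ``article_id`` and ``pub_date`` (ISO
    8601, day/month/year precision) and accepts optional ``specialty`` and
    ``evidence_category`` (integer 1–8) columns.  The edge table requires
    ``citing_id`` and ``cited_id``.  Duplicate edges are collapsed and
    self-citations dropped, each with a logged warning; an edge naming an
    unknown article, a duplicate article id, or an unparseable date is a
    hard error.
    """
    rows = _read_table(node_table)
    if rows and not {"article_id", "pub_date"} <= rows[0].keys():
        raise ValueError(
            f"{node_table}: node table must have columns article_id, pub_date"
        )
    records = []
    for i, row in enumerate(rows, start=2):
        try:
            date = parse_pub_date(row["pub_date"])
        except ValueError as exc:
            raise ValueError(f"{node_table} row {i}: {exc}") from exc
        cat_raw = (row.get("evidence_category") or "").strip()
        specialty = (row.get("specialty") or "").strip() or None
        records.append(
            ArticleRecord(
                article_id=row["article_id"].strip(),
                pub_date=date,
                specialty=specialty,
                evidence_category=int(cat_raw) if cat_raw else None,
            )
        )
    edge_rows = _read_table(edge_table)
    if edge_rows and not {"citing_id", "cited_id"} <= edge_rows[0].keys():
        raise ValueError(
            f"{edge_table}: edge table must have columns citing_id, cited_id"
        )
    edges = [
        (row["citing_id"].strip(), row["cited_id"].strip()) for row in edge_rows
    ]
    return CitationGraph(records, edges)


def extract_cascade(graph: CitationGraph, seed_id: str) -> Cascade:
    """Extract the diffusion cascade rooted at ``seed_id``.

    Members are the seed plus every article with a directed citation path
    to it; edges are all corpus edges with both endpoints among the members.
    """
    if seed_id not in graph:
        raise KeyError(f"unknown seed_id: {seed_id!r}")
    members = frozenset(nx.ancestors(graph.graph, seed_id)) | {seed_id}
    induced = graph.graph.subgraph(members)
    return Cascade(
        seed_id=seed_id,
        member_ids=frozenset(members),
        edges=frozenset(induced.edges()),
        records={m: graph.records[m] for m in members},
    )


def all_cascades(graph: CitationGraph, min_citations: int = 1) -> list[Cascade]:
    """One cascade per article with ≥ ``min_citations`` within-corpus citations.

    Articles that received at least one citation are the sources of
    innovation for which diffusion can be traced.  Output is ordered by
    seed id for determinism.
    """
    seeds = sorted(
        a for a in graph.records if graph.citation_count(a) >= min_citations
    )
    return [extract_cascade(graph, s) for s in seeds]


_EXPORT_FORMATS = ("graphml", "edge-list")


def export_graph(
    obj: CitationGraph | Cascade, path: str | Path, format: str = "edge-list"
) -> None:
    """Write a graph or cascade to ``path`` as GraphML or a two-column TSV.

    GraphML carries node attributes ``pub_date`` (ISO), ``specialty`` and
    ``evidence_category``; the edge list is round-trip safe via
    :func:`load_edge_list`.
    """
    if format not in _EXPORT_FORMATS:
        raise ValueError(
            f"unsupported export format {format!r}; supported: "
            + ", ".join(_EXPORT_FORMATS)
        )
    if isinstance(obj, Cascade):
        g = obj.subgraph()
        records: Mapping[str, ArticleRecord] = obj.records
    else:
        g = obj.graph
        records = obj.records
    path = Path(path)
    if format == "edge-list":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["citing_id", "cited_id"])
            for citing, cited in sorted(g.edges()):
                writer.writerow([citing, cited])
        return
    out = nx.DiGraph()
    for node in g.nodes():
        rec = records.get(node)
        attrs: dict[str, object] = {}
        if rec is not None:
            attrs["pub_date"] = rec.pub_date.isoformat()
            if rec.specialty is not None:
                attrs["specialty"] = rec.specialty
            if rec.evidence_category is not None:
                attrs["evidence_category"] = int(rec.evidence_category)
        out.add_node(node, **attrs)
    out.add_edges_from(g.edges())
    nx.write_graphml(out, path)


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read back an exported two-column edge list."""
    return [
        (row["citing_id"].strip(), row["cited_id"].strip())
        for row in _read_table(path)
    ]
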