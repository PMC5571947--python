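"""Per-cascade broadcast and virality metrics.

Broadcast popularity is captured by the number of citations the seed
article received from other cascade members (Cit_s) and the fraction of
those arriving within one year of the seed's publication (Cit_{s,year}).
Virality is captured by three structural measures of the cascade:

* **size** — the number of articles in the cascade, seed included;
* **structural depth** — the mean length of the shortest directed paths
  over all ordered member pairs connected by a directed path; deep
  cascades are multi-generational;
* **structural width** — the mean number of second-step citations divided
  by the mean number of (first-step) citations accrued by cascade members;
  zero for a star graph (no second neighbours) and large for widespread
  tree-like branching.

Depth and width are defined only for cascades with more than one article;
undefined values propagate as ``None`` (missing data downstream), never as
zero, so that size-1 cascades do not bias group distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .corpus_graph import Cascade

__all__ = [
    "BroadcastMetrics",
    "ViralityMetrics",
    "seed_citations",
    "first_year_fraction",
    "cascade_size",
    "structural_depth",
    "structural_width",
    "node_step_ratio",
    "metrics_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "seed_id",
    "specialty",
    "seed_citations",
    "first_year_fraction",
    "size",
    "structural_depth",
    "structural_width",
]


@dataclass(frozen=True)
class BroadcastMetrics:
    seed_citations: int
    first_year_fraction: float | None

    def __post_init__(self) -> None:
        if (self.first_year_fraction is None) != (self.seed_citations == 0):
            raise ValueError(
                "first_year_fraction must be undefined exactly when the seed "
                "has zero citations"
            )


@dataclass(frozen=True)
class ViralityMetrics:
    size: int
    structural_depth: float | None
    structural_width: float | None

    def __post_init__(self) -> None:
        if (self.structural_depth is None) != (self.size == 1):
            raise ValueError("structural_depth undefined iff size == 1")
        if (self.structural_width is None) != (self.size == 1):
            raise ValueError("structural_width undefined iff size == 1")


def seed_citations(cascade: Cascade) -> int:
    """Citations received by the seed from other cascade members (Cit_s)."""
    return sum(1 for _, cited in cascade.edges if cited == cascade.seed_id)


def first_year_fraction(
    cascade: Cascade, window_days: int = 365
) -> float | None:
    """Fraction of the seed's citations arriving within ``window_days``.

    A direct citer counts as within the window when its publication date is
    between the seed's date (inclusive) and ``window_days`` after it
    (inclusive).  Citers dated before the seed count toward Cit_s but never
    toward the window.  Undefined (``None``) when the seed has no citations.
    """
    total = seed_citations(cascade)
    if total == 0:
        return None
    seed_date = cascade.records[cascade.seed_id].pub_date
    in_window = 0
    for citing, cited in cascade.edges:
        if cited != cascade.seed_id:
            continue
        rec = cascade.records.get(citing)
        if rec is None or rec.pub_date is None:
            raise ValueError(f"article {citing!r} has no publication date")
        lag = (rec.pub_date - seed_date).days
        if 0 <= lag <= window_days:
            in_window += 1
    return in_window / total


def cascade_size(cascade: Cascade) -> int:
    """Number of articles in the cascade, seed included (SC_s)."""
    return cascade.n


def structural_depth(cascade: Cascade) -> float | None:
    """Mean shortest directed path length over connected ordered pairs (sd_Cs).

    Over all ordered pairs (i, j), i ≠ j, of members for which a directed
    path i → … → j exists in the induced subgraph, returns the sum of
    shortest-path lengths divided by the number of such pairs.  Unreachable
    pairs are excluded from both numerator and denominator.  Undefined for
    single-article cascades.
    """
    if cascade.n == 1:
        return None
    g = cascade.subgraph()
    total = 0
    n_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                total += dist
                n_pairs += 1
    if n_pairs == 0:  # cannot occur for a valid cascade with n > 1
        return None
    return total / n_pairs


def _step_counts(g: nx.DiGraph, second_step: str) -> tuple[dict, dict]:
    """First- and second-step citation counts per node of ``g``.

    First-step citations of i = in-degree of i (direct citers within the
    cascade).  Second-step citations of i = number of directed walks of
    length exactly 2 ending at i, i.e. the citations received by i's direct
    citers summed with multiplicity.  ``second_step="distinct"`` counts
    distinct articles at directed distance exactly 2 instead of walks.
    """
    if second_step not in ("walks", "distinct"):
        raise ValueError("second_step must be 'walks' or 'distinct'")
    first = dict(g.in_degree())
    second: dict = {}
    for node in g.nodes():
        if second_step == "walks":
            second[node] = sum(g.in_degree(c) for c in g.predecessors(node))
        else:
            dist2 = {
                anc
                for c in g.predecessors(node)
                for anc in g.predecessors(c)
            }
            # distance exactly 2: drop nodes that also cite directly
            second[node] = len(dist2 - set(g.predecessors(node)) - {node})
    return first, second


def structural_width(
    cascade: Cascade, second_step: str = "walks"
) -> float | None:
    """Ratio of mean second-step to mean first-step citations (sw_Cs).

    Because both means divide by the member count, the ratio reduces to
    total second-step walks / total induced edges.  Zero for a star graph;
    undefined for single-article cascades.
    """
    if cascade.n == 1:
        return None
    first, second = _step_counts(cascade.subgraph(), second_step)
    total_first = sum(first.values())
    if total_first == 0:  # cannot occur for a valid cascade with n > 1
        return None
    return sum(second.values()) / total_first


def node_step_ratio(
    cascade: Cascade, node_id: str, second_step: str = "walks"
) -> float | None:
    """Second-step over first-step citations of one member.

    Undefined (``None``) for members with no citers.  This is the per-node
    quantity used to size nodes in cascade drawings.
    """
    if node_id not in cascade.member_ids:
        raise KeyError(f"unknown node_id: {node_id!r}")
    first, second = _step_counts(cascade.subgraph(), second_step)
    if first[node_id] == 0:
        return None
    return second[node_id] / first[node_id]


def metrics_table(
    cascades: list[Cascade],
    window_days: int = 365,
    second_step: str = "walks",
) -> pd.DataFrame:
    """All broadcast and virality metrics, one row per cascade.

    Columns: seed_id, specialty (of the seed), seed_citations,
    first_year_fraction, size, structural_depth, structural_width.  Rows
    are sorted by seed id; undefined values are NaN and serialize as empty
    CSV cells.
    """
    rows = []
    for c in sorted(cascades, key=lambda c: c.seed_id):
        seed_rec = c.records.get(c.seed_id)
        rows.append(
            {
                "seed_id": c.seed_id,
                "specialty": seed_rec.specialty if seed_rec else None,
                "seed_citations": seed_citations(c),
                "first_year_fraction": first_year_fraction(c, window_days),
                "size": cascade_size(c),
                "structural_depth": structural_depth(c),
                "structural_width": structural_width(c, second_step),
            }
        )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return df.astype(
        {
            "seed_citations": "int64" if len(df) else "float64",
            "first_year_fraction": "float64",
            "size": "int64" if len(df) else "float64",
            "structural_depth": "float64",
            "structural_width": "float64",
        }
    )
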