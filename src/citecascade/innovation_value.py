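"""Innovation-funnel categories and the evidence-weighted innovation index.

Surgical innovation progresses through an ordinal funnel of eight
implementation stages, from idea description and laboratory evaluation
through pre-clinical (cadaveric, animal) studies up to the strongest
clinical levels of evidence.  Each article carries an ordinal category
c ∈ 1..8 (1 = earliest stage, 8 = final implementation stage).

For a group (specialty) g, with p_cg the number of its publications in
category c and P_c = Σ_g p_cg the category total across groups, the
unnormalized innovation score is

    u_g = Σ_c  c · p_cg / P_c        (categories with P_c = 0 skipped)

and the innovation index rescales so the top group scores exactly 100:

    i_g = 100 · u_g / max_g u_g.

The index rewards groups whose publication mass sits deep in the funnel:
a category contributes its ordinal position weighted by the group's share
of all publications at that stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .corpus_graph import ArticleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "N_CATEGORIES",
    "DEFAULT_FUNNEL_LABELS",
    "FunnelMap",
    "SpecialtyCounts",
    "InnovationIndexResult",
    "tally_counts",
    "innovation_index",
    "funnel_report",
]

N_CATEGORIES = 8

#: Default stage labels, earliest (1) to final implementation (8): three
#: pre-clinical stages followed by the five clinical levels of evidence,
#: weakest (level 5) to strongest (level 1).  Configurable via FunnelMap.
DEFAULT_FUNNEL_LABELS = (
    "idea description / laboratory evaluation",
    "cadaveric study",
    "animal study",
    "clinical evidence level 5",
    "clinical evidence level 4",
    "clinical evidence level 3",
    "clinical evidence level 2",
    "clinical evidence level 1",
)


@dataclass(frozen=True)
class FunnelMap:
    """Ordered labels of the 8 funnel stages; position c runs 1..8."""

    labels: tuple[str, ...] = DEFAULT_FUNNEL_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != N_CATEGORIES:
            raise ValueError(
                f"funnel map must list exactly {N_CATEGORIES} categories, "
                f"got {len(self.labels)}"
            )
        if len(set(self.labels)) != N_CATEGORIES:
            raise ValueError("funnel category labels must be distinct")

    def label(self, position: int) -> str:
        if not 1 <= position <= N_CATEGORIES:
            raise ValueError(f"category position must be in 1..8, got {position}")
        return self.labels[position - 1]

    @classmethod
    def from_file(cls, path: str | Path) -> "FunnelMap":
        """Load an ordered 8-label list from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        if isinstance(data, dict):
            data = data.get("categories", data.get("labels"))
        if not isinstance(data, list):
            raise ValueError(
                f"{path}: expected a list of 8 category labels "
                "(optionally under a 'categories' key)"
            )
        return cls(tuple(str(x) for x in data))


class SpecialtyCounts:
    """Publication counts p[c][g] per funnel category c and group g.

    Backed by a DataFrame with index 1..8 (category position) and one
    column per group; ``category_totals`` gives P_c.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        if (table.values < 0).any():
            raise ValueError("counts must be non-negative")
        table = table.reindex(range(1, N_CATEGORIES + 1), fill_value=0)
        self.table = table.astype(int)
        self.table.index.name = "category"

    @property
    def groups(self) -> list[str]:
        return list(self.table.columns)

    @property
    def category_totals(self) -> pd.Series:
        """P_c = Σ_g p_cg, recomputed from the table."""
        return self.table.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.table.values.sum())


@dataclass(frozen=True)
class InnovationIndexResult:
    """Per-group innovation index (max exactly 100) and unnormalized score."""

    index: pd.Series
    unnormalized: pd.Series

    def ranking(self) -> list[str]:
        """Groups ordered by descending index, label-ordered within ties."""
        df = self.index.rename("index").reset_index()
        df.columns = ["group", "index"]
        df = df.sort_values(["index", "group"], ascending=[False, True])
        return df["group"].tolist()


def tally_counts(articles: Iterable[ArticleRecord]) -> SpecialtyCounts:
    """Tally publications into the category × group count matrix.

    Articles lacking a specialty or an evidence category are excluded with
    a logged count; an out-of-range category is a hard error (guarded by
    :class:`~citecascade.corpus_graph.ArticleRecord` at construction and
    re-checked here for raw inputs).
    """
    counts: dict[str, dict[int, int]] = {}
    n_skipped = 0
    for art in articles:
        if art.specialty is None or art.evidence_category is None:
            n_skipped += 1
            continue
        c = int(art.evidence_category)
        if not 1 <= c <= N_CATEGORIES:
            raise ValueError(
                f"article {art.article_id!r}: evidence_category {c} "
                f"outside 1..{N_CATEGORIES}"
            )
        counts.setdefault(art.specialty, {})[c] = (
            counts.get(art.specialty, {}).get(c, 0) + 1
        )
    if n_skipped:
        logger.info(
            "excluded %d article(s) missing specialty or evidence category",
            n_skipped,
        )
    table = pd.DataFrame(
        {g: pd.Series(cs) for g, cs in sorted(counts.items())},
        index=range(1, N_CATEGORIES + 1),
    ).fillna(0)
    return SpecialtyCounts(table)


def innovation_index(counts: SpecialtyCounts) -> InnovationIndexResult:
    """Compute the innovation index i_g for every group.

    Raises
    ------
    ValueError
        If all counts are zero (the index is undefined).
    """
    if counts.total == 0:
        raise ValueError("innovation index undefined for all-zero counts")
    totals = counts.category_totals
    positions = pd.Series(counts.table.index, index=counts.table.index)
    # share of each category owned by each group, weighted by position c;
    # empty categories (P_c = 0) contribute nothing to any group
    nonzero = totals > 0
    shares = counts.table.loc[nonzero].div(totals[nonzero], axis=0)
    unnormalized = shares.mul(positions[nonzero], axis=0).sum(axis=0)
    # divide before scaling so the top group is exactly 100.0
    index = (unnormalized / unnormalized.max()) * 100.0
    return InnovationIndexResult(
        index=index.rename("index"), unnormalized=unnormalized.rename("u")
    )


def funnel_report(
    counts: SpecialtyCounts, funnel: FunnelMap | None = None
) -> pd.DataFrame:
    """Long-format funnel flows for external Sankey rendering.

    One row per nonzero p[c][g]: group, category_position, category_label,
    count, and the group's innovation index; ordered by index descending,
    then category descending.  All-zero counts raise (index undefined).
    """
    funnel = funnel or FunnelMap()
    result = innovation_index(counts)
    rows = []
    for g in counts.groups:
        for c in counts.table.index:
            n = int(counts.table.at[c, g])
            if n > 0:
                rows.append(
                    {
                        "group": g,
                        "category_position": int(c),
                        "category_label": funnel.label(int(c)),
                        "count": n,
                        "index": float(result.index[g]),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["group", "category_position", "category_label", "count", "index"],
    )
    return df.sort_values(
        ["index", "category_position"], ascending=[False, False]
    ).reset_index(drop=True)
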