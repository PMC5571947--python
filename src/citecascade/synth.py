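"""Deterministic synthetic citation corpora for testing and demonstration.

Real citation corpora of innovation diffusion contain many seed articles,
each heading a dated cascade whose shape ranges from star-like broadcast
(one burst of first-generation citers) to multi-generational viral
branching.  This module generates such corpora from three cascade
archetypes:

* **star** — one seed with k direct citers; the broadcast limit (width 0);
* **chain** — a single line of n successive citations; the minimal
  multi-generational case with known closed-form depth (n + 1)/3;
* **branching** — a Galton–Watson tree with Poisson(λ) offspring per node
  up to a maximum number of generations; the viral regime.

Every generator is deterministic given its seed, emits exactly the
node/edge CSV dialect consumed by :func:`citecascade.corpus_graph.load_corpus`,
and produces acyclic edge sets by construction (each citer is dated after
the article it cites).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

NODE_COLUMNS = ["article_id", "pub_date", "specialty", "evidence_category"]
EDGE_COLUMNS = ["citing_id", "cited_id"]

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "make_star",
    "make_chain",
    "make_branching",
    "make_corpus",
    "demo_config",
    "config_from_yaml",
    "write_corpus",
]

LagModel = int | tuple[int, int]


def _sample_lag(lag_days: LagModel, rng: np.random.Generator | None) -> int:
    if isinstance(lag_days, int):
        return lag_days
    lo, hi = lag_days
    if rng is None:
        raise ValueError("a random generator is required for a lag range")
    return int(rng.integers(lo, hi + 1))


def _tables(
    nodes: list[tuple[str, _dt.date, str | None, int | None]],
    edges: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes_df = pd.DataFrame(
        [
            {
                "article_id": a,
                "pub_date": d.isoformat(),
                "specialty": s if s is not None else "",
                "evidence_category": c if c is not None else "",
            }
            for a, d, s, c in nodes
        ],
        columns=NODE_COLUMNS,
    )
    edges_df = pd.DataFrame(edges, columns=EDGE_COLUMNS)
    return nodes_df, edges_df


def make_star(
    k: int,
    seed_date: _dt.date = _dt.date(2000, 1, 1),
    lag_days: LagModel = 180,
    prefix: str = "star",
    specialty: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A seed plus k leaves each citing it — the broadcast archetype."""
    if k < 1:
        raise ValueError(f"star needs k >= 1 leaves, got {k}")
    seed_id = f"{prefix}-0000"
    nodes = [(seed_id, seed_date, specialty, None)]
    edges = []
    for i in range(1, k + 1):
        leaf = f"{prefix}-{i:04d}"
        date = seed_date + _dt.timedelta(days=_sample_lag(lag_days, rng))
        nodes.append((leaf, date, specialty, None))
        edges.append((leaf, seed_id))
    return _tables(nodes, edges)


def make_chain(
    n: int,
    seed_date: _dt.date = _dt.date(2000, 1, 1),
    lag_days: LagModel = 180,
    prefix: str = "chain",
    specialty: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A path a_1 → a_2 → … → a_n of successive citations.

    The seed is a_n (the earliest article); the cascade seeded there has
    size n and depth (n + 1)/3.
    """
    if n < 2:
        raise ValueError(f"chain needs n >= 2 articles, got {n}")
    ids = [f"{prefix}-{i:04d}" for i in range(1, n + 1)]
    dates: dict[str, _dt.date] = {ids[-1]: seed_date}
    for i in range(n - 2, -1, -1):  # a_{n-1} down to a_1, each citing the next
        dates[ids[i]] = dates[ids[i + 1]] + _dt.timedelta(
            days=_sample_lag(lag_days, rng)
        )
    nodes = [(a, dates[a], specialty, None) for a in ids]
    edges = [(ids[i], ids[i + 1]) for i in range(n - 1)]
    return _tables(nodes, edges)


def make_branching(
    offspring_mean: float,
    max_generations: int,
    rng_seed: int | np.random.Generator,
    seed_date: _dt.date = _dt.date(2000, 1, 1),
    lag_days: LagModel = 180,
    prefix: str = "tree",
    specialty: str | None = None,
    rewire_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A Galton–Watson citation tree — the viral archetype.

    The seed is the root; each node in generation t < ``max_generations``
    receives Poisson(``offspring_mean``) citing children dated one lag
    later.  With ``rewire_rate`` > 0 each non-root node additionally cites
    a uniformly chosen earlier ancestor on its path with that probability,
    adding cross-generational shortcuts while preserving acyclicity.
    """
    if offspring_mean < 0:
        raise ValueError("offspring mean must be non-negative")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    root = f"{prefix}-0000"
    nodes = [(root, seed_date, specialty, None)]
    edges: list[tuple[str, str]] = []
    ancestry: dict[str, list[str]] = {root: []}
    frontier = [root]
    dates = {root: seed_date}
    counter = 1
    for _gen in range(max_generations):
        next_frontier = []
        for parent in frontier:
            n_children = int(rng.poisson(offspring_mean))
            for _ in range(n_children):
                child = f"{prefix}-{counter:04d}"
                counter += 1
                dates[child] = dates[parent] + _dt.timedelta(
                    days=_sample_lag(lag_days, rng)
                )
                nodes.append((child, dates[child], specialty, None))
                edges.append((child, parent))
                ancestry[child] = ancestry[parent] + [parent]
                next_frontier.append(child)
                grand = ancestry[parent]
                if grand and rewire_rate > 0 and rng.random() < rewire_rate:
                    target = grand[int(rng.integers(len(grand)))]
                    edges.append((child, target))
        frontier = next_frontier
        if not frontier:
            break
    return _tables(nodes, edges)


@dataclass(frozen=True)
class GroupSpec:
    """One specialty-labeled group of cascades in a generated corpus."""

    name: str
    style: str  # star | chain | branching
    cascades: int
    params: dict = field(default_factory=dict)
    evidence_probs: tuple[float, ...] = (0.125,) * 8
    lag_days: LagModel = (30, 365)

    def __post_init__(self) -> None:
        if self.style not in ("star", "chain", "branching"):
            raise ValueError(f"unknown cascade style {self.style!r}")
        probs = np.asarray(self.evidence_probs, dtype=float)
        if probs.size != 8 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"group {self.name!r}: evidence_probs must be 8 non-negative "
                "values summing to 1"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full corpus recipe; identical configs produce byte-identical corpora."""

    rng_seed: int
    groups: tuple[GroupSpec, ...]
    seed_date: _dt.date = _dt.date(2000, 1, 1)


def make_corpus(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the union of per-group cascades with disjoint id spaces.

    Every article carries its group name as specialty and an evidence
    category sampled from the group's category probabilities.
    """
    rng = np.random.default_rng(config.rng_seed)
    node_frames, edge_frames = [], []
    for group in config.groups:
        for i in range(group.cascades):
            prefix = f"{group.name}-c{i:03d}"
            if group.style == "star":
                nodes, edges = make_star(
                    k=int(group.params.get("k", 10)),
                    seed_date=config.seed_date,
                    lag_days=group.lag_days,
                    prefix=prefix,
                    specialty=group.name,
                    rng=rng,
                )
            elif group.style == "chain":
                nodes, edges = make_chain(
                    n=int(group.params.get("n", 5)),
                    seed_date=config.seed_date,
                    lag_days=group.lag_days,
                    prefix=prefix,
                    specialty=group.name,
                    rng=rng,
                )
            else:
                nodes, edges = make_branching(
                    offspring_mean=float(group.params.get("offspring_mean", 2.0)),
                    max_generations=int(group.params.get("max_generations", 5)),
                    rng_seed=rng,
                    seed_date=config.seed_date,
                    lag_days=group.lag_days,
                    prefix=prefix,
                    specialty=group.name,
                    rewire_rate=float(group.params.get("rewire_rate", 0.0)),
                )
            cats = rng.choice(
                np.arange(1, 9), size=len(nodes), p=group.evidence_probs
            )
            nodes = nodes.assign(evidence_category=cats)
            node_frames.append(nodes)
            edge_frames.append(edges)
    if not node_frames:
        return (
            pd.DataFrame(columns=NODE_COLUMNS),
            pd.DataFrame(columns=EDGE_COLUMNS),
        )
    return (
        pd.concat(node_frames, ignore_index=True),
        pd.concat(edge_frames, ignore_index=True),
    )


def seed_ids(config: GeneratorConfig) -> list[str]:
    """Ids of the generated root (seed) articles, one per cascade.

    The root of a star or branching cascade is its first article; a chain
    a_1 → … → a_n is seeded at a_n, the article everything traces back to.
    """
    out = []
    for group in config.groups:
        for i in range(group.cascades):
            prefix = f"{group.name}-c{i:03d}"
            if group.style == "chain":
                n = int(group.params.get("n", 5))
                out.append(f"{prefix}-{n:04d}")
            else:
                out.append(f"{prefix}-0000")
    return out


def demo_config(rng_seed: int = 0) -> GeneratorConfig:
    """Planted two-group corpus: one viral, one broadcast specialty.

    The viral group is 10 Galton–Watson cascades (λ = 2, 5 generations)
    with evidence mass at the final implementation stage; the broadcast
    group is 10 stars (k = 20) with mass at the earliest stage.  By
    construction the viral group should rank first on size, depth and
    width, and the innovation index should rank it first as well.
    """
    return GeneratorConfig(
        rng_seed=rng_seed,
        groups=(
            GroupSpec(
                name="viral",
                style="branching",
                cascades=10,
                params={"offspring_mean": 2.0, "max_generations": 5},
                evidence_probs=(0, 0, 0, 0, 0, 0, 0.1, 0.9),
            ),
            GroupSpec(
                name="broadcast",
                style="star",
                cascades=10,
                params={"k": 20},
                evidence_probs=(0.9, 0.1, 0, 0, 0, 0, 0, 0),
            ),
        ),
    )


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML.

    Expected shape::

        rng_seed: 7
        seed_date: 2000-01-01
        groups:
          - name: viral
            style: branching
            cascades: 10
            params: {offspring_mean: 2.0, max_generations: 5}
            evidence_probs: [0, 0, 0, 0, 0, 0, 0.1, 0.9]
            lag_days: [30, 365]
    """
    data = yaml.safe_load(Path(path).read_text())
    groups = []
    for g in data["groups"]:
        lag = g.get("lag_days", (30, 365))
        if isinstance(lag, list):
            lag = (int(lag[0]), int(lag[1]))
        groups.append(
            GroupSpec(
                name=str(g["name"]),
                style=str(g["style"]),
                cascades=int(g["cascades"]),
                params=dict(g.get("params", {})),
                evidence_probs=tuple(
                    float(p) for p in g.get("evidence_probs", (0.125,) * 8)
                ),
                lag_days=lag,
            )
        )
    seed_date = data.get("seed_date", _dt.date(2000, 1, 1))
    if isinstance(seed_date, str):
        seed_date = _dt.date.fromisoformat(seed_date)
    return GeneratorConfig(
        rng_seed=int(data["rng_seed"]), groups=tuple(groups), seed_date=seed_date
    )


def write_corpus(
    nodes: pd.DataFrame, edges: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write node/edge tables as the CSV dialect load_corpus consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    node_path = out / "nodes.csv"
    edge_path = out / "edges.csv"
    nodes.to_csv(node_path, index=False)
    edges.to_csv(edge_path, index=False)
    return node_path, edge_path
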