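import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from citecascade.corpus_graph import ArticleRecord, Cascade

from oracles import transitive_ancestors

BASE_DATE = dt.date(2000, 1, 1)


def make_records(ids, dates=None, specialty=None, categories=None):
    dates = dates or {}
    categories = categories or {}
    return {
        a: ArticleRecord(
            article_id=a,
            pub_date=dates.get(a, BASE_DATE),
            specialty=specialty,
            evidence_category=categories.get(a),
        )
        for a in ids
    }


def build_cascade(seed, edges, dates=None, extra_members=()):
    """Cascade with membership derived by the brute-force ancestor oracle."""
    members = transitive_ancestors(edges, seed) | {seed} | set(extra_members)
    induced = {(u, v) for u, v in edges if u in members and v in members}
    return Cascade(
        seed_id=seed,
        member_ids=frozenset(members),
        edges=frozenset(induced),
        records=make_records(members, dates=dates),
    )


@pytest.fixture
def star5():
    """Seed 's' with 5 leaves, all dated 30 days after the seed."""
    edges = {(f"l{i}", "s") for i in range(5)}
    dates = {f"l{i}": BASE_DATE + dt.timedelta(days=30) for i in range(5)}
    return build_cascade("s", edges, dates=dates)


@pytest.fixture
def chain3():
    """a → b → c seeded at c."""
    return build_cascade("c", {("a", "b"), ("b", "c")})


@pytest.fixture
def chain4():
    """a → b → c → d seeded at d."""
    return build_cascade("d", {("a", "b"), ("b", "c"), ("c", "d")})


@pytest.fixture
def singleton():
    return build_cascade("solo", set())
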