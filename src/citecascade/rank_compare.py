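"""Group rankings, pairwise distribution tests, and exact-p rank correlation.

Groups (e.g. surgical specialties) are ranked by the median of their
per-cascade metric distribution, with ties broken by the 75th percentile —
then, to guarantee a total deterministic order, by the 90th percentile and
finally by label; the decisive statistic is recorded per row.  Pairs of
distributions are compared with Mann–Whitney U or two-sample
Kolmogorov–Smirnov tests, with Benjamini–Hochberg FDR adjustment across
the pairwise matrix.

Ranking similarity is measured by Spearman's rho, Kendall's tau-b, and
Kendall's coefficient of concordance W.  Because the number of ranked
groups is small, p-values are computed by permutation: full enumeration of
all label permutations up to a size threshold, and seeded Monte-Carlo
sampling above it, with the mode always recorded in the result.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MetricDistribution",
    "RankingTable",
    "PairwiseTestMatrix",
    "RankCorrelationResult",
    "build_distributions",
    "rank_groups",
    "pairwise_tests",
    "fdr_adjust",
    "rank_correlation",
    "kendall_w",
    "as_rank_vector",
    "ranks_from_scores",
    "load_ranking_csv",
]

_EPS = 1e-12


@dataclass(frozen=True)
class MetricDistribution:
    """Defined metric values of one group, with cached quantiles.

    Quantiles use linear interpolation between order statistics; the
    definition matters because rankings break ties on the 75th percentile.
    """

    group: str
    values: tuple[float, ...]

    @property
    def usable(self) -> bool:
        return len(self.values) > 0

    def quantile(self, q: float) -> float:
        if not self.usable:
            raise ValueError(f"group {self.group!r} has no defined values")
        return float(np.quantile(self.values, q))

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    @property
    def p75(self) -> float:
        return self.quantile(0.75)

    @property
    def p90(self) -> float:
        return self.quantile(0.90)


@dataclass(frozen=True)
class RankingTable:
    """Groups in rank order with the tie-break statistic that was decisive."""

    table: pd.DataFrame  # columns: group, median, p75, p90, tie_break

    def labels(self) -> list[str]:
        return self.table["group"].tolist()

    def ranks(self) -> pd.Series:
        """Rank 1 = top of the table, indexed by group label."""
        return pd.Series(
            np.arange(1, len(self.table) + 1), index=self.table["group"].values
        )


@dataclass(frozen=True)
class PairwiseTestMatrix:
    """Symmetric raw/adjusted p-value matrices over group pairs."""

    test: str
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    adjust: str

    def to_long(self) -> pd.DataFrame:
        """One row per unordered pair: group_a, group_b, raw_p, adjusted_p,
        significant."""
        groups = list(self.raw_p.index)
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "raw_p": self.raw_p.at[a, b],
                "adjusted_p": self.adjusted_p.at[a, b],
                "significant": bool(self.significant.at[a, b]),
            }
            for a, b in itertools.combinations(groups, 2)
        ]
        return pd.DataFrame(
            rows, columns=["group_a", "group_b", "raw_p", "adjusted_p", "significant"]
        )


@dataclass(frozen=True)
class RankCorrelationResult:
    """A rank-correlation or concordance statistic with its permutation p.

    ``p_mode`` is ``"enumeration"`` (exact, fully reproducible) or
    ``"monte_carlo"`` (reproducible given ``seed``); ``n_permutations`` is
    the enumeration size or the replicate count.
    """

    method: str
    coefficient: float
    p_value: float
    p_mode: str
    n_permutations: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# distributions and rankings


def build_distributions(
    metrics: pd.DataFrame, metric: str, group_field: str = "specialty"
) -> list[MetricDistribution]:
    """Per-group distributions of one metric column, missing values dropped.

    Groups whose values are all undefined (e.g. depth for a group of
    size-1 cascades) are excluded with a logged notice.
    """
    for col in (metric, group_field):
        if col not in metrics.columns:
            raise KeyError(f"column {col!r} not in metrics table")
    out = []
    for group, sub in metrics.groupby(group_field, sort=True):
        values = sub[metric].dropna()
        if values.empty:
            logger.info(
                "group %r excluded: no defined values for %r", group, metric
            )
            continue
        out.append(MetricDistribution(str(group), tuple(float(v) for v in values)))
    return out


def rank_groups(distributions: Sequence[MetricDistribution]) -> RankingTable:
    """Rank groups by descending median with recorded tie-breaks.

    Ties on the median are broken by the 75th percentile; remaining ties
    by the 90th percentile and finally by ascending label, so the order is
    total and deterministic.  Each row records the deepest statistic that
    was needed to distinguish it from some other group
    (``none``/``p75``/``p90``/``label``).
    """
    usable = [d for d in distributions if d.usable]
    if not usable:
        raise ValueError("no usable distributions to rank")
    rows = []
    medians = [d.median for d in usable]
    pairs75 = [(d.median, d.p75) for d in usable]
    triples = [(d.median, d.p75, d.p90) for d in usable]
    for d in usable:
        if medians.count(d.median) == 1:
            tb = "none"
        elif pairs75.count((d.median, d.p75)) == 1:
            tb = "p75"
        elif triples.count((d.median, d.p75, d.p90)) == 1:
            tb = "p90"
        else:
            tb = "label"
        rows.append(
            {
                "group": d.group,
                "median": d.median,
                "p75": d.p75,
                "p90": d.p90,
                "tie_break": tb,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["median", "p75", "p90", "group"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return RankingTable(table.reset_index(drop=True))


def pairwise_tests(
    distributions: Sequence[MetricDistribution],
    test: str = "mann_whitney",
    alpha: float = 0.05,
    adjust: str = "fdr",
) -> PairwiseTestMatrix:
    """Two-sided pairwise tests between all group distributions.

    ``mann_whitney`` uses the exact null for small tie-free samples and the
    tie/continuity-corrected normal approximation otherwise (scipy's
    ``method="auto"``); ``kolmogorov_smirnov`` uses the two-sample
    asymptotic p-value.  With ``adjust="fdr"`` significance is judged on
    Benjamini–Hochberg adjusted p-values.
    """
    if test not in ("mann_whitney", "kolmogorov_smirnov"):
        raise ValueError(f"unknown test {test!r}")
    if adjust not in ("none", "fdr"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    usable = [d for d in distributions if d.usable]
    if len(usable) < 2:
        raise ValueError("need at least two usable distributions")
    for d in usable:
        if len(d.values) < 2:
            raise ValueError(
                f"group {d.group!r} has fewer than two values; cannot test"
            )
    groups = [d.group for d in usable]
    raw = pd.DataFrame(np.nan, index=groups, columns=groups)
    pairs = list(itertools.combinations(range(len(usable)), 2))
    pvals = []
    for i, j in pairs:
        x, y = usable[i].values, usable[j].values
        if test == "mann_whitney":
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        else:
            res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
        p = float(res.pvalue)
        pvals.append(p)
        raw.iloc[i, j] = raw.iloc[j, i] = p
    adj_vals = fdr_adjust(pvals) if adjust == "fdr" else list(pvals)
    adjusted = pd.DataFrame(np.nan, index=groups, columns=groups)
    for (i, j), q in zip(pairs, adj_vals):
        adjusted.iloc[i, j] = adjusted.iloc[j, i] = q
    judged = adjusted if adjust == "fdr" else raw
    significant = (judged < alpha).where(~judged.isna(), False)
    return PairwiseTestMatrix(
        test=test,
        raw_p=raw,
        adjusted_p=adjusted,
        significant=significant,
        alpha=alpha,
        adjust=adjust,
    )


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# rank vectors


def as_rank_vector(
    ranking: Sequence[str] | Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Normalize a ranking to a rank vector indexed by label.

    An ordered sequence of labels (best first) becomes ranks 1..n; a
    mapping or Series of label → rank is used as given (midranks allowed).
    """
    if isinstance(ranking, pd.Series):
        return ranking.astype(float)
    if isinstance(ranking, Mapping):
        return pd.Series({str(k): float(v) for k, v in ranking.items()})
    labels = [str(x) for x in ranking]
    if len(set(labels)) != len(labels):
        raise ValueError("ordered ranking contains duplicate labels")
    return pd.Series(np.arange(1, len(labels) + 1, dtype=float), index=labels)


def ranks_from_scores(
    scores: Mapping[str, float] | pd.Series, higher_is_better: bool = True
) -> pd.Series:
    """Midrank vector from raw scores (rank 1 = best)."""
    s = pd.Series(dict(scores), dtype=float)
    vals = -s.values if higher_is_better else s.values
    return pd.Series(stats.rankdata(vals), index=s.index)


def load_ranking_csv(path: str | Path) -> pd.Series:
    """Read an external two-column (label, rank-or-value) ranking file."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (label, rank or value)")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))


def _aligned(
    a: Sequence[str] | Mapping[str, float] | pd.Series,
    b: Sequence[str] | Mapping[str, float] | pd.Series,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ra, rb = as_rank_vector(a), as_rank_vector(b)
    if set(ra.index) != set(rb.index):
        only_a = sorted(set(ra.index) - set(rb.index))
        only_b = sorted(set(rb.index) - set(ra.index))
        raise ValueError(
            f"ranking label sets differ; only in first: {only_a}, "
            f"only in second: {only_b}"
        )
    labels = sorted(ra.index)
    return ra[labels].to_numpy(), rb[labels].to_numpy(), labels


# ---------------------------------------------------------------------------
# vectorized coefficients over permutation matrices


def _spearman_vec(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman rho of fixed rank vector ``a`` against each row of ``B``.

    Computed as the Pearson correlation of the rank vectors, which handles
    midranks; every row of ``B`` is a permutation of the same multiset, so
    its norm is constant.
    """
    ac = a - a.mean()
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(ac) * np.linalg.norm(Bc[0])
    if denom < _EPS:
        raise ValueError("rank correlation undefined for constant rankings")
    return (Bc @ ac) / denom


def _kendall_vec(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kendall tau-b of fixed rank vector ``a`` against each row of ``B``."""
    n = a.size
    ii, jj = np.triu_indices(n, k=1)
    sa = np.sign(a[ii] - a[jj])
    SB = np.sign(B[:, ii] - B[:, jj])
    s = SB @ sa
    n0 = ii.size
    n1 = int(np.sum(sa == 0))
    n2 = int(np.sum(SB[0] == 0))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom < _EPS:
        raise ValueError("rank correlation undefined for constant rankings")
    return s / denom


def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _mc_perm_matrix(
    n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    return np.argsort(rng.random((reps, n)), axis=1)


def rank_correlation(
    ranking_a: Sequence[str] | Mapping[str, float] | pd.Series,
    ranking_b: Sequence[str] | Mapping[str, float] | pd.Series,
    method: str = "spearman",
    exact_threshold: int = 8,
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> RankCorrelationResult:
    """Spearman's rho or Kendall's tau-b with a permutation p-value.

    The two-sided p-value is the share of label permutations of the second
    ranking whose |coefficient| is at least the observed |coefficient|:
    full enumeration of all n! permutations for n ≤ ``exact_threshold``,
    otherwise Monte-Carlo with ``mc_reps`` replicates and a mandatory
    ``seed``.
    """
    if method not in ("spearman", "kendall_tau"):
        raise ValueError(f"unknown method {method!r}")
    a, b, _labels = _aligned(ranking_a, ranking_b)
    n = a.size
    coef_fn = _spearman_vec if method == "spearman" else _kendall_vec
    observed = float(coef_fn(a, b[None, :])[0])
    if n <= exact_threshold:
        perms = _perm_matrix(n)
        mode, used_seed = "enumeration", None
    else:
        if seed is None:
            raise ValueError("seed is required for Monte-Carlo p-values")
        perms = _mc_perm_matrix(n, mc_reps, np.random.default_rng(seed))
        mode, used_seed = "monte_carlo", seed
    coefs = coef_fn(a, b[perms])
    p = float(np.mean(np.abs(coefs) >= abs(observed) - _EPS))
    return RankCorrelationResult(
        method=method,
        coefficient=observed,
        p_value=p,
        p_mode=mode,
        n_permutations=perms.shape[0],
        seed=used_seed,
    )


def _w_statistic(R: np.ndarray) -> float:
    """Kendall's W for an m × n rank matrix with midrank tie correction."""
    m, n = R.shape
    sums = R.sum(axis=0)
    S = float(((sums - sums.mean()) ** 2).sum())
    T = 0.0
    for row in R:
        _, counts = np.unique(row, return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = m * m * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError("Kendall's W undefined: all items tied in every ranking")
    return 12.0 * S / denom


def kendall_w(
    rankings: Iterable[Sequence[str] | Mapping[str, float] | pd.Series],
    exact_threshold: int = 8,
    enumeration_cap: int = 50_000,
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> RankCorrelationResult:
    """Kendall's coefficient of concordance W across m ≥ 2 rankings.

    W = 12·S / (m²·(n³ − n) − m·T) with S the sum of squared deviations of
    the per-item rank sums and T the midrank tie correction.  The
    permutation null permutes every ranking but the first (W is invariant
    under a common relabeling); the one-sided p-value is P[W ≥ observed].
    Enumeration is used when n ≤ ``exact_threshold`` and the (n!)^(m−1)
    permutation space fits in ``enumeration_cap``; Monte-Carlo (seed
    required) otherwise.
    """
    vectors = [as_rank_vector(r) for r in rankings]
    if len(vectors) < 2:
        raise ValueError("Kendall's W needs at least two rankings")
    label_sets = [frozenset(v.index) for v in vectors]
    if len(set(label_sets)) != 1:
        diff = sorted(set.union(*map(set, label_sets)) - set.intersection(*map(set, label_sets)))
        raise ValueError(f"ranking label sets differ; mismatched labels: {diff}")
    labels = sorted(vectors[0].index)
    R = np.vstack([v[labels].to_numpy() for v in vectors])
    m, n = R.shape
    observed = _w_statistic(R)
    space = math.factorial(n) ** (m - 1)
    if n <= exact_threshold and space <= enumeration_cap:
        count = 0
        perms = list(itertools.permutations(range(n)))
        for combo in itertools.product(perms, repeat=m - 1):
            perm_R = np.vstack(
                [R[0]] + [R[k + 1][list(p)] for k, p in enumerate(combo)]
            )
            if _w_statistic(perm_R) >= observed - _EPS:
                count += 1
        return RankCorrelationResult(
            method="kendall_w",
            coefficient=observed,
            p_value=count / space,
            p_mode="enumeration",
            n_permutations=space,
            seed=None,
        )
    if seed is None:
        raise ValueError("seed is required for Monte-Carlo p-values")
    rng = np.random.default_rng(seed)
    sums = np.broadcast_to(R[0], (mc_reps, n)).copy()
    for k in range(1, m):
        idx = _mc_perm_matrix(n, mc_reps, rng)
        sums += R[k][idx]
    S = ((sums - sums.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    T = sum(
        float((np.unique(row, return_counts=True)[1] ** 3
               - np.unique(row, return_counts=True)[1]).sum())
        for row in R
    )
    denom = m * m * (n**3 - n) - m * T
    W = 12.0 * S / denom
    p = float(np.mean(W >= observed - _EPS))
    return RankCorrelationResult(
        method="kendall_w",
        coefficient=observed,
        p_value=p,
        p_mode="monte_carlo",
        n_permutations=mc_reps,
        seed=seed,
    )
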