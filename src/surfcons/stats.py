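"""Rank-based comparison of variant groups (conservation grade, SASA).

The omnibus comparison is the Kruskal-Wallis test with the standard tie
correction

    H = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2,
    H_corrected = H / (1 - sum(t^3 - t) / (N^3 - N)),

with the p-value from the chi-square distribution on k-1 degrees of
freedom (an exact permutation p is available for small samples).  Pairwise
follow-up uses two-sided Mann-Whitney/Wilcoxon rank-sum tests: exact
enumeration of all assignments when both groups have n <= 8, otherwise the
tie-corrected normal approximation; unadjusted by default with an optional
Holm correction.  Group summaries are mean ± sample (n-1) standard
deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "GroupedSample",
    "GroupComparison",
    "rank_with_ties",
    "kruskal_wallis",
    "summarize",
    "pairwise_tests",
    "compare_groups",
    "plot_group_summary",
]

ALPHA = 0.05  # conventional significance level


@dataclass
class GroupedSample:
    """Named groups of finite scalar values."""

    groups: Mapping[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if not np.isfinite(arr).all():
                raise ParameterError(f"group {name!r} contains non-finite values")
            clean[name] = arr
        self.groups = clean

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    def nonempty(self) -> "GroupedSample":
        return GroupedSample({k: v for k, v in self.groups.items() if len(v)})


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Midranks of a pooled sample (tied values share their average rank);
    the rank sum is always N(N+1)/2."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot rank an empty sample")
    return sps.rankdata(arr, method="average")


def _tie_correction(pooled: np.ndarray) -> float:
    n = pooled.size
    if n < 2:
        return 1.0
    _vals, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))


def _h_statistic(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """(tie-corrected H, tie correction factor)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    correction = _tie_correction(pooled)
    if correction == 0.0:
        return 0.0, correction  # all values identical
    return h / correction, correction


def summarize(sample: GroupedSample) -> pd.DataFrame:
    """Per-group n, mean and sample standard deviation (ddof=1; NaN for
    singletons, where the SD is undefined)."""
    rows = []
    for name, vals in sample.groups.items():
        if len(vals) == 0:
            raise ParameterError(f"group {name!r} is empty")
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise rank-sum tests


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of the C(n1+n2, n1)
    group assignments (midranks, so ties are handled exactly)."""
    pooled = np.concatenate([x, y])
    ranks = rank_with_ties(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    expect = n1 * (len(pooled) + 1) / 2.0
    dev = abs(obs - expect)
    total = 0
    hits = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - expect) >= dev - 1e-9:
            hits += 1
    return hits / total


def _asymptotic_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided normal-approximation Mann-Whitney with tie correction."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def pairwise_tests(
    sample: GroupedSample,
    adjust: str | None = None,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests.

    method per pair: 'exact' (full enumeration) when both n <= exact_max_n,
    else 'asymptotic' (normal approximation, tie-corrected).  ``adjust``
    may be 'holm' for a Holm step-down correction; default is unadjusted,
    and the method used is recorded per row.
    """
    names = sample.names
    if len(names) < 2:
        raise ParameterError("need at least two groups for pairwise tests")
    rows = []
    for a, b in itertools.combinations(names, 2):
        x, y = sample.groups[a], sample.groups[b]
        ranks = rank_with_ties(np.concatenate([x, y]))
        u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0  # Mann-Whitney U
        if np.array_equal(np.sort(x), np.sort(y)):
            p, method = 1.0, "degenerate-identical"
        elif len(x) <= exact_max_n and len(y) <= exact_max_n:
            p, method = _exact_ranksum_p(x, y), "exact"
        else:
            p, method = _asymptotic_ranksum_p(x, y), "asymptotic"
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
             "u_statistic": float(u), "p_value": p, "method": method}
        )
    table = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
        table["adjustment"] = "holm"
    elif adjust is not None:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    else:
        table["adjustment"] = "none"
    return table


# ---------------------------------------------------------------------------
# omnibus test


@dataclass
class GroupComparison:
    """Result of the k-group rank comparison."""

    h: float
    df: int
    p_value: float
    tie_correction: float
    summary_table: pd.DataFrame
    pairwise: pd.DataFrame
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(self.p_value < ALPHA)

    def summary(self) -> str:
        lines = [
            "Kruskal-Wallis rank comparison",
            "==============================",
            f"H = {self.h:.4f} on {self.df} df, tie correction "
            f"{self.tie_correction:.4f}",
            f"p = {self.p_value:.4g}  "
            f"({'significant' if self.significant else 'not significant'} "
            f"at {ALPHA})",
            "",
            self.summary_table.to_string(index=False),
            "",
            "pairwise (two-sided rank-sum):",
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "H": self.h,
            "df": self.df,
            "p_value": self.p_value,
            "tie_correction": self.tie_correction,
            "significant_at_0.05": self.significant,
            "groups": self.summary_table.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def kruskal_wallis(
    sample: GroupedSample,
    *,
    p_method: str = "chi2",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis test across the sample's groups.

    ``p_method='chi2'`` uses the chi-square approximation on k-1 df (the
    standard software default); ``'permutation'`` draws a Monte-Carlo
    permutation null of the corrected H (for small samples).
    """
    groups = [sample.groups[n] for n in sample.names]
    k = len(groups)
    if k < 2:
        raise ParameterError("need at least two groups")
    for name, g in zip(sample.names, groups):
        if len(g) == 0:
            raise ParameterError(f"group {name!r} is empty")
    n_total = sum(len(g) for g in groups)
    if n_total < k + 1:
        raise ParameterError("too few observations for a k-group test")

    h, correction = _h_statistic(groups)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        p = 1.0
    elif p_method == "chi2":
        p = float(sps.chi2.sf(h, k - 1))
    elif p_method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        sizes = [len(g) for g in groups]
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h_perm, _c = _h_statistic(parts)
            if h_perm >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")

    return GroupComparison(
        h=h,
        df=k - 1,
        p_value=p,
        tie_correction=correction,
        summary_table=summarize(sample),
        pairwise=pairwise_tests(sample),
    )


def compare_groups(values: Mapping[str, Sequence[float]], **kw) -> GroupComparison:
    """Convenience wrapper: dict of group -> values."""
    return kruskal_wallis(GroupedSample(dict(values)), **kw)


# ---------------------------------------------------------------------------
# figure


def plot_group_summary(
    comparisons: Mapping[str, GroupComparison],
    path: str | None = None,
):
    """Bar chart of group means ± SD per measured quantity, with pairwise
    significance stars (* p<0.05, ** p<0.01, *** p<0.001)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(comparisons), figsize=(4.5 * len(comparisons), 4))
    if len(comparisons) == 1:
        axes = [axes]
    for ax, (title, comp) in zip(axes, comparisons.items()):
        tab = comp.summary_table
        x = np.arange(len(tab))
        ax.bar(x, tab["mean"], yerr=tab["sd"].fillna(0.0), capsize=4,
               color=["white", "grey", "black"][: len(tab)],
               edgecolor="black")
        ax.set_xticks(x)
        ax.set_xticklabels([f"{g}\n(n={n})" for g, n in zip(tab["group"], tab["n"])])
        ax.set_title(title)
        stars = []
        for _i, row in comp.pairwise.iterrows():
            p = row["p_value"]
            if p < 0.001:
                mark = "***"
            elif p < 0.01:
                mark = "**"
            elif p < ALPHA:
                mark = "*"
            else:
                continue
            stars.append(f"{row['group_a']} vs {row['group_b']}: {mark}")
        if stars:
            ax.text(0.02, 0.98, "\n".join(stars), transform=ax.transAxes,
                    va="top", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
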