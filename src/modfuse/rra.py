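"""Robust rank aggregation (RRA) across resampled rankings.

An item that is consistently near the top of many ranked lists receives a
small score rho, defined as the minimum over k of the probability that the
k-th order statistic of uniform ranks falls at or below the item's observed
k-th best normalised rank: rho = min_k P(Beta(k, n-k+1) <= r_(k)).  rho is a
bound, not a p-value; it is corrected by multiplying by the number of lists
the item appears in (Bonferroni over k), and corrected scores are adjusted
across items by Benjamini-Hochberg.

Normalised ranks are positions divided by the size of the ranked universe,
so partial lists (an item missing from some resamples) are handled by
simply contributing no rank from those lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError


def beta_score(
    sorted_normalised_ranks: Sequence[float], n_total: int | None = None
) -> float:
    """rho = min_k P(Beta(k, n-k+1) <= r_k) for ascending ranks in (0, 1].

    ``n_total`` is the length of the full rank vector; when the observed
    ranks are a prefix of a longer vector whose remaining entries are
    unobserved (an item missing from some lists), pass the total list count
    so the unobserved worst ranks still shape the order-statistic null.
    """
    r = np.asarray(sorted_normalised_ranks, dtype=float)
    if r.size == 0:
        raise ValidationError("beta_score requires at least one rank")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValidationError("normalised ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise ValidationError("ranks must be sorted ascending")
    n = r.size if n_total is None else int(n_total)
    if n < r.size:
        raise ValidationError("n_total smaller than the number of ranks")
    k = np.arange(1, r.size + 1)
    return float(np.min(stats.beta.cdf(r, k, n - k + 1)))


def beta_score_permutation(
    sorted_normalised_ranks: Sequence[float],
    n_total: int | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo version of :func:`beta_score`: each order-statistic
    probability is estimated from random uniform rank vectors instead of the
    analytic beta CDF.  The two modes must agree within Monte-Carlo error."""
    r = np.asarray(sorted_normalised_ranks, dtype=float)
    if r.size == 0:
        raise ValidationError("beta_score requires at least one rank")
    n = r.size if n_total is None else int(n_total)
    rng = np.random.default_rng(seed)
    draws = np.sort(rng.random((n_draws, n)), axis=1)[:, : r.size]
    probs = (draws <= r[None, :]).mean(axis=0)
    return float(np.min(probs))


def rho_null_cdf(rho: float, n: int) -> float:
    """Exact null probability that the minimum beta order-statistic score of
    ``n`` uniform ranks falls at or below ``rho``.

    rho itself is a minimum over correlated candidates, so it is not a
    p-value; this computes P(RHO <= rho) exactly via the boundary-crossing
    recursion on the empirical counts N(b_k), where b_k is the rank value at
    which candidate k equals rho.  Used where a calibrated per-item p-value
    is needed (e.g. CpG-to-gene aggregation); the consensus stages use the
    simpler Bonferroni bound rho * n.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if rho <= 0:
        return 0.0
    if rho >= 1:
        return 1.0
    if n > 100:  # factorial overflow regime; the bound is tight here anyway
        return float(min(1.0, rho * n))
    k = np.arange(1, n + 1)
    b = stats.beta.ppf(rho, k, n - k + 1)  # ascending boundary
    w = np.diff(np.concatenate([[0.0], b]))
    # f[j] accumulates P(N(b_k) = j, no crossing so far) / j!-style terms
    f = np.zeros(n + 1)
    f[0] = 1.0
    from math import factorial

    for step in range(1, n + 1):
        new = np.zeros(n + 1)
        for j in range(0, step):  # crossing means N(b_step) >= step
            acc = 0.0
            for i in range(0, j + 1):
                if f[i] != 0.0:
                    acc += f[i] * w[step - 1] ** (j - i) / factorial(j - i)
            new[j] = acc
        f = new
    tail = 0.0
    for j in range(0, n + 1):
        if f[j] != 0.0:
            tail += f[j] * (1 - b[-1]) ** (n - j) / factorial(n - j)
    survive = tail * factorial(n)
    return float(min(1.0, max(0.0, 1.0 - survive)))


@dataclass
class RankAggregationResult:
    table: pd.DataFrame  # item_id, rho, corrected_p, bh_adjusted_p (sorted)

    def significant(self, fdr: float) -> list[str]:
        t = self.table
        return t.loc[t["bh_adjusted_p"] < fdr, "item_id"].tolist()


def aggregate_ranks(
    lists: Sequence[Sequence[str]],
    universe_size: int,
    n_lists: int | None = None,
    method: str = "analytic",
    n_draws: int = 100_000,
    seed: int = 0,
) -> RankAggregationResult:
    """Aggregate ranked item lists (best first) into consensus scores.

    Each list ranks some or all items of a universe of ``universe_size``
    items; the normalised rank of the item at position i (1-based) is
    i / universe_size.  An item absent from a list is treated as unobserved
    at the worst rank: it contributes no beta candidate from that list, but
    the order-statistic null and the Bonferroni factor still count every
    list, keeping sporadic appearances conservative.  ``n_lists`` overrides
    the list count when some tested lists are empty (e.g. resamples whose
    models were screened out): those still count toward the null.
    """
    if len(lists) == 0:
        raise ValidationError("aggregate_ranks requires at least one list")
    for lst in lists:
        if len(lst) > universe_size:
            raise ValidationError(
                f"universe_size {universe_size} smaller than a list of length {len(lst)}"
            )
        if len(set(lst)) != len(lst):
            raise ValidationError("duplicate items within a ranked list")
    ranks: dict[str, list[float]] = {}
    for lst in lists:
        for pos, item in enumerate(lst, start=1):
            ranks.setdefault(item, []).append(pos / universe_size)
    if n_lists is None:
        n_lists = len(lists)
    elif n_lists < len(lists):
        raise ValidationError("n_lists smaller than the number of lists given")
    rows = []
    for item in sorted(ranks):
        r = np.sort(np.asarray(ranks[item]))
        if method == "analytic":
            rho = beta_score(r, n_total=n_lists)
        elif method == "permutation":
            rho = beta_score_permutation(r, n_total=n_lists,
                                         n_draws=n_draws, seed=seed)
        else:
            raise ValidationError(f"unknown method {method!r}")
        corrected = min(1.0, rho * n_lists)
        rows.append((item, rho, corrected, len(r)))
    table = pd.DataFrame(rows, columns=["item_id", "rho", "corrected_p", "n_lists"])
    table["bh_adjusted_p"] = adjust_bh(table["corrected_p"].to_numpy())
    table = table.sort_values(
        ["corrected_p", "item_id"], kind="mergesort"
    ).reset_index(drop=True)
    return RankAggregationResult(table)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_items_by_pvalue(
    p_values: pd.Series, statistics: pd.Series | None = None
) -> list[str]:
    """Order item ids by p ascending; ties broken by |statistic| descending
    then id lexicographic, so rankings are deterministic."""
    absstat = (
        statistics.abs().reindex(p_values.index).fillna(0.0)
        if statistics is not None
        else pd.Series(0.0, index=p_values.index)
    )
    keyed = sorted(
        (float(p_values[i]), -float(absstat[i]), str(i)) for i in p_values.index
    )
    return [item for _, _, item in keyed]
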