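"""Preranked gene-set enrichment.

Features are ordered by a signed association statistic (moderated t or
gene-level z), descending.  For a candidate set, a running sum walks the
ranked list: it rises by ``|stat|^q / sum_members |stat|^q`` at member
positions and falls by ``1 / (N - n_members)`` elsewhere.  The enrichment
score ES is the signed extreme deviation of that walk; significance comes
from random same-size member draws (gene-label permutation, as in fgsea),
with Benjamini-Hochberg adjustment across sets.  The leading edge of an
up-regulated set is its members at or before the peak; of a down-regulated
set, its members at or after the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection, ValidationError
from .rra import adjust_bh


@dataclass
class RankedList:
    """Feature ids ordered by statistic descending, ties broken by id."""

    ids: list[str]
    stats: np.ndarray

    @classmethod
    def from_series(cls, statistics: pd.Series) -> "RankedList":
        order = sorted(
            statistics.index, key=lambda i: (-float(statistics[i]), str(i))
        )
        return cls([str(i) for i in order],
                   statistics.loc[order].to_numpy(dtype=float))

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.stats):
            raise ValidationError("ids and stats lengths differ")
        if len(self.ids) < 2:
            raise ValidationError("ranked list needs at least 2 items")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in ranked list")
        self.stats = np.asarray(self.stats, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    peak_index: int  # 1-based position of the |running sum| maximum
    p_value: float
    adjusted_p: float
    size: int
    direction: str  # "up" | "down"
    leading_edge: list[str] = field(default_factory=list)


def _es_from_positions(
    positions: np.ndarray, absw: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ES for rows of sorted member positions (0-based).

    ``positions`` is (n_draws, s); ``absw`` is |stat|^q over the whole list.
    Returns (es, peak_pos_0based) per row.  The walk's extrema occur just
    before a member increment (minima candidates) or just after one (maxima
    candidates); the end value is exactly 0.
    """
    n_draws, s = positions.shape
    miss = 1.0 / (n_total - s)
    w = absw[positions]
    wsum = w.sum(axis=1, keepdims=True)
    # degenerate all-zero weights: fall back to equal weights (uniform hit)
    zero = wsum[:, 0] == 0
    if np.any(zero):
        w[zero] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    inc = w / wsum
    cum = np.cumsum(inc, axis=1)
    gaps = positions - np.arange(s)[None, :]  # non-members before each member
    bottoms = np.concatenate(
        [np.zeros((n_draws, 1)), cum[:, :-1]], axis=1
    ) - gaps * miss
    tops = bottoms + inc
    max_dev = np.maximum(tops.max(axis=1), 0.0)
    min_dev = np.minimum(bottoms.min(axis=1), 0.0)
    up = max_dev >= -min_dev
    es = np.where(up, max_dev, min_dev)
    peak = np.where(up, positions[np.arange(n_draws), tops.argmax(axis=1)],
                    positions[np.arange(n_draws), bottoms.argmin(axis=1)] - 1)
    return es, peak


def enrichment_score(
    ranked: RankedList, members: Iterable[str], weight_exponent: float = 1.0
) -> tuple[float, int]:
    """ES and 1-based peak position for one member set.

    Raises if no member is present in the list or the members cover the
    entire list (the miss decrement would be undefined).
    """
    members = set(members)
    mask = np.fromiter((i in members for i in ranked.ids), bool, len(ranked))
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValidationError("no set member present in the ranked list")
    if n_hit == len(ranked):
        raise ValidationError("set covers the entire ranked list")
    absw = np.abs(ranked.stats) ** weight_exponent
    hitw = np.where(mask, absw, 0.0)
    total = hitw.sum()
    if total == 0:  # all member stats zero: fall back to equal weights
        hitw = mask.astype(float)
        total = hitw.sum()
    inc = hitw / total
    dec = np.where(mask, 0.0, 1.0 / (len(ranked) - n_hit))
    run = np.cumsum(inc - dec)
    peak = int(np.argmax(np.abs(run)))
    mx, mn = run.max(), run.min()
    es = mx if mx >= -mn else mn
    return float(es), peak + 1


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_permutations: int = 2000,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation GSEA over a collection, BH-adjusted across tested sets.

    Per set the p-value is ``(1 + #{|ES_perm| >= |ES|, same sign}) /
    (1 + n_permutations)`` over random same-size member draws.  Sets whose
    present-member count falls outside [min_size, max_size] are skipped.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be at least 100")
    id_pos = {fid: i for i, fid in enumerate(ranked.ids)}
    absw = np.abs(ranked.stats) ** weight_exponent
    n_total = len(ranked)
    rng = np.random.default_rng(seed)

    tested: list[tuple[str, np.ndarray]] = []
    for set_id in sorted(sets):
        pos = np.sort(
            np.fromiter(
                (id_pos[m] for m in sets.members(set_id) if m in id_pos),
                dtype=int,
            )
        )
        if min_size <= pos.size <= max_size and pos.size < n_total:
            tested.append((set_id, pos))

    # share permutations across sets of equal size
    perm_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    results: list[EnrichmentResult] = []
    for set_id, pos in tested:
        s = pos.size
        es, peak1 = enrichment_score(
            ranked, {ranked.ids[i] for i in pos}, weight_exponent
        )
        peak = peak1 - 1
        if s not in perm_cache:
            draws = np.argpartition(
                rng.random((n_permutations, n_total)), s - 1, axis=1
            )[:, :s]
            draws = np.sort(draws, axis=1)
            perm_cache[s] = _es_from_positions(draws, absw, n_total)
        perm_es, _ = perm_cache[s]
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        extreme = np.abs(perm_es) >= abs(es)
        # one-sided among same-sign permutations, as in fgsea; keeps null
        # p-values uniform
        p = (1 + int(np.sum(same_sign & extreme))) / (1 + int(same_sign.sum()))
        results.append(
            EnrichmentResult(
                set_id=set_id, es=es, peak_index=peak + 1, p_value=p,
                adjusted_p=np.nan, size=s,
                direction="up" if es >= 0 else "down",
            )
        )
    if results:
        adj = adjust_bh([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
            r.leading_edge = extract_leading_edge(
                ranked, r, sets.members(r.set_id)
            )
    return results


def extract_leading_edge(
    ranked: RankedList, result: EnrichmentResult, members: Iterable[str]
) -> list[str]:
    """Members driving the ES: positions 1..peak for up-sets, peak..N for
    down-sets (1-based, inclusive), in list order."""
    if not 1 <= result.peak_index <= len(ranked):
        raise ValidationError(
            f"peak_index {result.peak_index} out of range for list of "
            f"length {len(ranked)}"
        )
    members = set(members)
    if result.direction == "up":
        window = ranked.ids[: result.peak_index]
    else:
        window = ranked.ids[result.peak_index - 1:]
    return [i for i in window if i in members]


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "es": [r.es for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "direction": [r.direction for r in results],
            "size": [r.size for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
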