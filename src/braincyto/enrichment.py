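"""Gene-set enrichment analysis on per-gene statistics.

Weighted Kolmogorov-Smirnov running-sum enrichment on a ranked statistic
(moderated t, B, or combined scores, where contradictory genes sit at 0).
Significance is assessed by gene-label permutation -- random sets of the
same size drawn from the analysis universe -- with separate p-values for
the positive (up-regulated) and negative (down-regulated) tails, BH
adjusted across sets within each direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from braincyto.diffexp import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag."""

    sets: dict[str, list[str]]
    source: str = ""
    dropped: list[str] = field(default_factory=list)

    def restrict(self, universe: pd.Index) -> "GeneSetCollection":
        """Intersect each set with the analysis universe; empty sets are
        dropped and logged."""
        kept, dropped = {}, []
        uni = set(universe)
        for name, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        return GeneSetCollection(sets=kept, source=self.source, dropped=dropped)


def enrichment_score(
    ranked_stats: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted KS enrichment score of one set against a ranked statistic.

    ``ranked_stats`` are the statistic values sorted in ranking order
    (descending); ``hit_positions`` are the 0-based positions of the set's
    genes in that ranking.  The score is the maximum-magnitude deviation of
    the hit running sum (|stat|^weight increments) over the miss running
    sum, and lies in [-1, 1].
    """
    es = _es_batch(ranked_stats, np.sort(hit_positions)[None, :], weight)
    return float(es[0])


def _es_batch(ranked_stats: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Enrichment scores for many same-size hit-position sets (rows of
    ``hits``, each sorted ascending)."""
    N = len(ranked_stats)
    m = hits.shape[1]
    if m == 0 or m >= N:
        raise ValueError("set size must be between 1 and universe size - 1")
    w = np.abs(ranked_stats) ** weight if weight != 0 else np.ones(N)
    ws = w[hits]
    totals = ws.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0
    if degenerate.any():  # all-zero weights: fall back to uniform increments
        ws = np.where(degenerate[:, None], 1.0, ws)
        totals = ws.sum(axis=1, keepdims=True)
    cw = np.cumsum(ws, axis=1) / totals

    k = np.arange(1, m + 1)[None, :]
    miss_at = (hits + 1 - k) / (N - m)  # misses seen once the k-th hit is included
    miss_before = (hits - (k - 1)) / (N - m)
    dev_at = cw - miss_at
    prev = np.concatenate([np.zeros((hits.shape[0], 1)), cw[:, :-1]], axis=1)
    dev_before = prev - miss_before

    dev = np.concatenate([dev_at, dev_before], axis=1)
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def gsea(
    stat: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    independent_nulls: bool = False,
) -> pd.DataFrame:
    """Per-set enrichment table on a ranked gene statistic.

    Genes are ranked by decreasing statistic (ties broken by gene
    identifier for a stable order).  Null enrichment scores come from
    ``n_perm`` random same-size sets (gene-label permutation), shared
    across sets of equal size unless ``independent_nulls`` (sharing is
    cheap but couples the p-values of equal-size sets); p-values use the
    +1 correction and are BH adjusted within each direction.
    """
    if len(stat) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not np.isfinite(stat.to_numpy(dtype=float)).all():
        raise ValueError("statistic contains non-finite values")
    restricted = sets.restrict(stat.index)

    order = sorted(stat.index, key=lambda g: (-stat[g], g))
    ranked = stat.loc[order].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(order)}
    N = len(order)

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    rows = []
    for name, members in restricted.sets.items():
        hp = np.sort([pos[g] for g in members])
        m = len(hp)
        if m >= N:
            continue
        es = float(_es_batch(ranked, hp[None, :], weight)[0])
        if independent_nulls or m not in null_cache:
            keys = rng.random((n_perm, N))
            H = np.sort(np.argpartition(keys, m, axis=1)[:, :m], axis=1)
            null_cache[m] = _es_batch(ranked, H, weight)
        null = null_cache[m]
        p_up = (1 + (null >= es).sum()) / (1 + n_perm)
        p_down = (1 + (null <= es).sum()) / (1 + n_perm)
        rows.append(
            {"set": name, "size": m, "es": es, "p_up": p_up, "p_down": p_down}
        )
    table = pd.DataFrame(rows, columns=["set", "size", "es", "p_up", "p_down"])
    if len(table):
        table["fdr_up"] = bh_fdr(table["p_up"].to_numpy())
        table["fdr_down"] = bh_fdr(table["p_down"].to_numpy())
    else:
        table["fdr_up"] = []
        table["fdr_down"] = []
    return table.set_index("set")
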