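"""Virtual-screening metrics on ranked score lists.

Enrichment factor at a top fraction, hit rate, ROC AUC (Mann–Whitney
formulation, ties count 1/2) and the Pearson correlation between predicted
score and measured pK over a top slice.  The top slice holds
``ceil(fraction · N)`` entries (never empty), and score ties are broken by
a seeded shuffle applied once when the ranking is built, so tied decoys
cannot be placed optimistically.

A metric that is undefined on its input (no actives, a missing class, zero
variance) returns ``None`` rather than a number; cross-fold aggregation
drops those entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class RankedList:
    """A screening ranking: entries sorted by descending predicted score."""

    entries: pd.DataFrame  # columns: molecule_id, score, is_active[, pk]

    def __post_init__(self) -> None:
        required = {"molecule_id", "score", "is_active"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"ranked list missing columns {sorted(missing)}")
        scores = self.entries["score"].to_numpy()
        if len(scores) and (np.diff(scores) > 0).any():
            raise ValueError("ranked list scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_actives(self) -> int:
        return int(self.entries["is_active"].sum())


def rank_entries(
    molecule_ids,
    scores,
    is_active,
    pk=None,
    *,
    seed: int = 0,
) -> RankedList:
    """Build a RankedList, breaking score ties by a seeded pre-shuffle."""
    df = pd.DataFrame(
        {
            "molecule_id": np.asarray(molecule_ids),
            "score": np.asarray(scores, dtype=float),
            "is_active": np.asarray(is_active, dtype=bool),
        }
    )
    if pk is not None:
        df["pk"] = np.asarray(pk, dtype=float)
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))]
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return RankedList(df)


def _top_size(n: int, fraction: float) -> int:
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.ceil(fraction * n))


def enrichment_factor(ranked: RankedList, fraction: float) -> float | None:
    """Active fraction in the top ``fraction`` of the list over the random
    hit rate; ``None`` when the list has no actives."""
    n = len(ranked)
    if n == 0:
        raise ValueError("empty ranked list")
    total_actives = ranked.n_actives
    if total_actives == 0:
        return None
    top = _top_size(n, fraction)
    hits = int(ranked.entries["is_active"].iloc[:top].sum())
    return (hits / top) / (total_actives / n)


def hit_rate(ranked: RankedList, fraction: float) -> float:
    """Percentage of actives within the top slice of the ranking."""
    n = len(ranked)
    if n == 0:
        raise ValueError("empty ranked list")
    top = _top_size(n, fraction)
    hits = int(ranked.entries["is_active"].iloc[:top].sum())
    return 100.0 * hits / top


def roc_auc(ranked: RankedList) -> float | None:
    """ROC AUC via the Mann–Whitney statistic (average ranks, so tied
    active-inactive pairs contribute 1/2); ``None`` if a class is absent."""
    y = ranked.entries["is_active"].to_numpy()
    scores = ranked.entries["score"].to_numpy()
    n_act = int(y.sum())
    n_inact = len(y) - n_act
    if n_act == 0 or n_inact == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[y].sum() - n_act * (n_act + 1) / 2
    return float(u / (n_act * n_inact))


def top_fraction_correlation(ranked: RankedList, fraction: float) -> float | None:
    """Pearson correlation between predicted score and measured/imputed pK
    over the top slice; ``None`` with <3 entries or zero variance."""
    if "pk" not in ranked.entries.columns:
        raise ValueError("ranked list carries no measured pk column")
    top = _top_size(len(ranked), fraction)
    sub = ranked.entries.iloc[:top].dropna(subset=["pk"])
    if len(sub) < 3:
        return None
    x = sub["score"].to_numpy()
    y = sub["pk"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
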