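"""Fuse topology and localization into the LDS score and rank proteins.

LDS(v) = alpha * ND_f(v) + (1 - alpha) * SCS(v), where ND_f is the
min-max-normalized local fuzzy fractal dimension and SCS the subcellular
compartment score.  alpha = 1 reduces the ranking to pure topology,
alpha = 0 to pure localization.  Proteins are ranked in descending LDS
order; ties (common, because SCS takes few distinct values) are broken
by descending network degree and then ascending protein ID so that the
ranking is fully deterministic.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ldsrank.evaluation import topk_essential_count

log = logging.getLogger(__name__)


def minmax_normalize(values: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalization (x - min) / (max - min) onto [0, 1].

    A constant map normalizes to all zeros; an empty map is an error.
    """
    if not values:
        raise ValueError("cannot normalize an empty map")
    lo = min(values.values())
    hi = max(values.values())
    if hi == lo:
        return {k: 0.0 for k in values}
    span = hi - lo
    return {k: (x - lo) / span for k, x in values.items()}


def rank_proteins(
    scores: Mapping[str, float],
    degrees: Mapping[str, int] | None = None,
) -> list[str]:
    """Order protein IDs by descending score.

    Ties break by descending ``degrees`` (0 when absent), then ascending
    lexicographic ID, so repeated calls give an identical order.
    """
    if not scores:
        raise ValueError("cannot rank an empty score map")
    deg = degrees or {}
    return sorted(scores, key=lambda p: (-scores[p], -deg.get(p, 0), p))


def lds_scores(
    nd_f: Mapping[str, float],
    scs: Mapping[str, float],
    alpha: float,
    degrees: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-protein LDS scores with a deterministic 1-based rank attached.

    ``nd_f`` defines the protein set; proteins missing from ``scs`` get
    SCS = 0.0 (the null-annotation rule).  Returns a DataFrame with
    columns protein_id, nd_f, scs, lds, rank, sorted by rank, with
    ``alpha`` recorded in ``DataFrame.attrs``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    lds = {
        p: alpha * nd_f[p] + (1.0 - alpha) * scs.get(p, 0.0) for p in nd_f
    }
    order = rank_proteins(lds, degrees)
    frame = pd.DataFrame(
        {
            "protein_id": order,
            "nd_f": [nd_f[p] for p in order],
            "scs": [scs.get(p, 0.0) for p in order],
            "lds": [lds[p] for p in order],
            "rank": range(1, len(order) + 1),
        }
    )
    frame.attrs["alpha"] = alpha
    return frame


def rank_lds(
    net: nx.Graph,
    lffd_map: Mapping[str, float],
    scs_map: Mapping[str, float],
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Full fusion step: normalize LFFD, combine with SCS, rank.

    Returns the :func:`lds_scores` frame with an extra ``lffd`` column
    holding the raw (un-normalized) dimension.
    """
    nd_f = minmax_normalize(lffd_map)
    degrees = dict(net.degree())
    frame = lds_scores(nd_f, scs_map, alpha, degrees)
    frame.insert(1, "lffd", [lffd_map[p] for p in frame["protein_id"]])
    return frame


def alpha_sweep(
    net: nx.Graph,
    lffd_map: Mapping[str, float],
    scs_map: Mapping[str, float],
    alphas: Sequence[float],
    essentials: set[str],
    ks: Iterable[int],
) -> pd.DataFrame:
    """Top-k essential counts over a grid of alpha values.

    For each alpha the network is re-ranked and, for each cutoff k, the
    number of true essentials among the top k is counted.  Duplicate
    alpha values are collapsed with a warning.  Returns a DataFrame with
    columns alpha, k, essential_count (one row per alpha x k pair).
    """
    uniq: list[float] = []
    for a in alphas:
        if a in uniq:
            log.warning("duplicate alpha %s dropped from sweep", a)
        else:
            uniq.append(a)
    ks = list(ks)
    rows = []
    for a in uniq:
        ranking = list(rank_lds(net, lffd_map, scs_map, a)["protein_id"])
        for k in ks:
            rows.append(
                {
                    "alpha": a,
                    "k": k,
                    "essential_count": topk_essential_count(ranking, essentials, k),
                }
            )
    return pd.DataFrame(rows)
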