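"""Hypergeometric over-representation analysis with BH adjustment.

For a query gene set of size n drawn from a universe of size N, a
collection of size K overlapping the query in k genes gets the upper-tail
p-value P(X >= k), X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg
step-up adjustment is applied across all tested collections.

The recommended universe is the set of m6A-modified genes (any assigned
peak in either group), not the whole annotation: enrichment of a subset
of methylated genes should be judged against what could have been
methylated and detected.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_enrich", "bh_adjust"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test each collection for over-representation in the query set.

    The query must be a subset of the universe; collections are
    intersected with the universe before testing.  Returns a DataFrame
    (set_name, k, K, n, N, p_value, q_value) sorted by p ascending, with
    q-values BH-adjusted across all tested collections.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query gene set")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query contains {len(stray)} genes outside the universe, e.g. {sorted(stray)[:3]}")
    N, n = len(universe_set), len(query_set)
    rows = []
    for set_name in sorted(collections):
        members = set(collections[set_name]) & universe_set
        K = len(members)
        k = len(members & query_set)
        # upper tail P(X >= k); sf(k-1) includes k itself
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": set_name, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N", "p_value", "q_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
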