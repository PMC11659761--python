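"""Hypergeometric over-representation of gene sets.

For a query of size n drawn from a universe of size N, a gene set covering
K universe genes, and k query genes inside the set, the enrichment p-value
is the hypergeometric upper tail ``P[X >= k]``. The universe defaults to
the detectable genes of the experiment that produced the query (not the
genome), and each collection set is intersected with the universe before
testing. BH step-up q-values are reported across all tested sets;
depletion is not tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .errors import ConfigError


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric p-value ``P[X >= k]`` for overlap ``k``
    between a size-``n`` draw and ``K`` marked items out of ``N``."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ConfigError(f"inconsistent hypergeometric configuration "
                          f"(k={k}, N={N}, K={K}, n={n})")
    if k == 0:
        return 1.0  # the upper tail includes 0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Test each collection set for over-representation in the query.

    ``query`` must be a subset of ``universe``. Returns one row per set
    with k, K, n, N, the upper-tail p and the BH q, sorted by (q, p, name).
    Sets with no universe member are skipped.
    """
    universe = frozenset(str(g) for g in universe)
    query = frozenset(str(g) for g in query)
    if not universe:
        raise ConfigError("empty universe")
    if not query:
        raise ConfigError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ConfigError(f"query genes outside the universe: {extra[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name in collection.names():
        members = collection[name] & universe
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_pvalue(k, N, K, n)})
    if not rows:
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "p", "q"])
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return (table.sort_values(["q", "p", "set"], kind="mergesort")
                 .reset_index(drop=True))
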