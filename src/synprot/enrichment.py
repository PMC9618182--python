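"""Over-representation analysis over GMT gene-set collections.

For a query list of n proteins drawn from a universe of N, a gene set
with K annotated members and k query hits is scored with the upper-tail
hypergeometric probability P(X >= k) and the fold enrichment
(k/n)/(K/N).  P-values are adjusted by Benjamini-Hochberg step-up within
the collection.  Only over-representation (the upper tail) is tested.

The universe defaults to the intersection of the analysis-ready dataset
with the collection's annotation space, mirroring how web enrichment
tools treat a user-supplied background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

__all__ = ["GeneSetCollection", "hypergeom_enrich", "bh_fdr"]

ENRICHMENT_COLUMNS = [
    "set_name",
    "k",
    "n",
    "K",
    "N",
    "fold_enrichment",
    "p_value",
    "fdr",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named identifier sets restricted to an explicit universe.

    On construction every set is intersected with the universe and empty
    sets are dropped; at least one non-empty set must remain.
    """

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        universe = frozenset(self.universe)
        if not universe:
            raise ConfigError("universe is empty")
        restricted = {
            name: frozenset(members) & universe for name, members in self.sets.items()
        }
        restricted = {name: m for name, m in restricted.items() if m}
        if not restricted:
            raise ConfigError("no gene set overlaps the universe")
        object.__setattr__(self, "sets", restricted)
        object.__setattr__(self, "universe", universe)

    @classmethod
    def from_gmt(
        cls, sets: Mapping[str, Iterable], universe: Iterable | None = None
    ) -> "GeneSetCollection":
        """Build a collection from parsed GMT sets.

        With ``universe=None`` the annotation space (union of all sets)
        is used as the universe.
        """
        frozen = {name: frozenset(m) for name, m in sets.items()}
        if universe is None:
            universe = frozenset().union(*frozen.values())
        return cls(sets=frozen, universe=frozenset(universe))


def hypergeom_enrich(query: Iterable, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    Query identifiers outside the universe are dropped (their count is
    reported via the ``n_dropped`` DataFrame attribute).  Rows are sorted
    by p-value ascending with BH FDR attached across all sets of the
    collection.

    Returns
    -------
    pandas.DataFrame
        Columns ``set_name, k, n, K, N, fold_enrichment, p_value, fdr``.

    Raises
    ------
    ConfigError
        If the query is empty after restriction to the universe.
    """
    query_set = frozenset(query)
    restricted = query_set & collection.universe
    n_dropped = len(query_set) - len(restricted)
    if not restricted:
        raise ConfigError("query has no identifiers inside the universe")

    N = len(collection.universe)
    n = len(restricted)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(restricted & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": (k / n) / (K / N),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df[ENRICHMENT_COLUMNS]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clamped to [0, 1].

    Raises
    ------
    ValueError
        If any p-value lies outside [0, 1].
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
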