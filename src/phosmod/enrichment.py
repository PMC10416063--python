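"""Over-representation of module members against named set databases.

Module membership is compared against GMT-format site-set or gene-set
databases with the hypergeometric upper tail: given a universe of N
identifiers of which K belong to the set, and a query of n module
members with k in the set, p = P(X >= k).  The same statistic serves
cross-cohort module-overlap testing (are two modules from different
cohorts drawn from the same underlying signal?), with identifiers
harmonized as "gene_site" strings.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .associations import benjamini_hochberg


def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for overlap k of a size-n draw against a
    size-K set in a size-N universe."""
    return float(hypergeom.sf(k - 1, N, K, n))


def set_overrepresentation(
    query: set,
    db: Mapping[str, set],
    universe: set,
) -> pd.DataFrame:
    """Test the query against every set in the database.

    The query must lie within the universe; each database set is
    intersected with the universe before testing (a set with empty
    intersection is skipped with a reason).  Returns one row per set with
    columns set, overlap, set_size, query_size, universe_size, p, adj_p,
    sorted by p.
    """
    if not query <= universe:
        raise ValueError("query identifiers must be a subset of the universe")
    N = len(universe)
    n = len(query)
    records, skipped = [], []
    for name, members in db.items():
        restricted = members & universe
        if not restricted:
            skipped.append(name)
            continue
        K = len(restricted)
        k = len(query & restricted)
        records.append((name, k, K, n, N, hypergeometric_tail(k, N, K, n)))
    out = pd.DataFrame(
        records,
        columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"],
    )
    if len(out):
        out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        out["adj_p"] = []
    out["skipped_empty_universe_intersection"] = False
    for name in skipped:
        out.loc[len(out)] = [name, 0, 0, n, N, float("nan"), float("nan"), True]
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def module_overlap_test(
    module_a: set,
    module_b: set,
    universe: set,
) -> float:
    """Hypergeometric upper-tail p for the overlap of two site sets.

    Both modules must be subsets of a shared identifier universe; cohorts
    must harmonize identifiers (gene_site strings) first.
    """
    if not (module_a <= universe and module_b <= universe):
        raise ValueError(
            "modules must be subsets of the universe; harmonize identifiers "
            "(gene_site strings) across cohorts first"
        )
    k = len(module_a & module_b)
    return hypergeometric_tail(k, len(universe), len(module_b), len(module_a))
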