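"""Hypergeometric over-representation of gene symbols in gene sets.

Given the set of gene symbols appearing in a connectome and a GMT
collection, each set is scored with the hypergeometric upper tail
P(X >= k) for drawing k of the set's K members in a query of size n
from a universe of N measured symbols, with Benjamini-Hochberg control
across sets. The default universe is the symbols measured in the
supplied omics layers, not the union of the collection — enrichment is
judged against what could have been observed.

An Enrichr-style combined score -ln(p) * z is provided for
compatibility when a rank-deviation z is available from an external
service; the package itself reports p and the odds ratio as primary
outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from omicnet.errors import ConfigError, EnrichmentError
from omicnet.io import GeneSetCollection

log = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def odds_ratio(k: int, N: int, K: int, n: int) -> float:
    """Enrichment odds ratio from the 2x2 overlap table (inf if undefined)."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        return float("inf") if a * d > 0 else 0.0
    return (a * d) / (b * c)


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Score every gene set against the query.

    Query symbols outside the universe are dropped with a warning; sets
    are restricted to the universe. Results (one row per set with
    overlap >= min_overlap; pass 0 to keep all) are sorted by p
    ascending with BH-adjusted p computed across every tested set.
    """
    universe = set(universe)
    dropped = set(query) - universe
    if dropped:
        log.warning(
            "enrich: dropped %d query symbols outside the universe", len(dropped)
        )
    query = set(query) & universe
    if not query:
        raise EnrichmentError("enrich: query empty after universe restriction")
    if min_overlap < 0:
        raise ConfigError("min_overlap: must be >= 0")

    N, n = len(universe), len(query)
    rows = []
    for name, (desc, members) in collection.sets.items():
        in_universe = [m for m in members if m in universe]
        K = len(in_universe)
        overlap = sorted(query.intersection(in_universe))
        k = len(overlap)
        if K == 0 or k < min_overlap:
            continue
        rows.append(
            {
                "set_name": name,
                "description": desc,
                "k_overlap": k,
                "n_query": n,
                "K_set": K,
                "N_universe": N,
                "p_value": hypergeom_upper_tail(k, N, K, n),
                "odds_ratio": odds_ratio(k, N, K, n),
                "overlap_genes": ";".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "description", "k_overlap", "n_query", "K_set",
                "N_universe", "p_value", "odds_ratio", "overlap_genes",
                "adjusted_p",
            ]
        )
    out = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(
        drop=True
    )


def combined_score(p_value: float, z: float) -> float:
    """Enrichr-style combined score: -ln(p) * z (requires a supplied z)."""
    if not (0.0 < p_value <= 1.0):
        raise ConfigError("p_value: must lie in (0, 1] for combined_score")
    return float(-np.log(p_value) * z)
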