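"""Hypergeometric over-representation analysis against user-supplied gene sets.

Given a query list (e.g. the differentially glycosylated proteins) and a
universe (by default every protein quantified in the glyco dataset, i.e.
conditioning on detectability), each gene set is tested with the upper
hypergeometric tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the set size within the universe, n the
query size and k the observed overlap.  Benjamini-Hochberg correction is
applied across the tested sets.  Symbols are matched case-insensitively
after trimming, since GMT files vary in capitalisation.
"""

from __future__ import annotations

import dataclasses
from typing import Collection, Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


@dataclasses.dataclass
class EnrichmentResult:
    set_name: str
    description: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_value: float
    bh_q: float
    overlap: tuple[str, ...]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exact, stable in log space."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def run_ora(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Collection[str],
) -> tuple[list[EnrichmentResult], list[str]]:
    """Test every gene set with >= 1 universe member; sort by p then name.

    Query symbols outside the universe are dropped and returned for
    logging.  An empty query-universe intersection is an error.
    """
    universe_norm = {_norm(g) for g in universe if g.strip()}
    if not universe_norm:
        raise ValueError("empty universe")
    query_norm: dict[str, str] = {}
    dropped: list[str] = []
    for g in query_genes:
        key = _norm(g)
        if key in universe_norm:
            query_norm.setdefault(key, g.strip())
        else:
            dropped.append(g)
    if not query_norm:
        raise ValueError("query has no overlap with the universe")

    N = len(universe_norm)
    n = len(query_norm)
    results: list[EnrichmentResult] = []
    for name, (description, members) in gene_sets.sets.items():
        members_in_universe = {_norm(m) for m in members} & universe_norm
        if not members_in_universe:
            continue
        overlap_keys = sorted(members_in_universe & set(query_norm))
        K = len(members_in_universe)
        k = len(overlap_keys)
        results.append(
            EnrichmentResult(
                set_name=name,
                description=description,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=hypergeometric_tail(k, K, n, N),
                bh_q=float("nan"),
                overlap=tuple(query_norm[g] for g in overlap_keys),
            )
        )
    if results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.bh_q = float(q)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results, dropped


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "description": r.description,
                "k_overlap": r.k,
                "K_set_size": r.K,
                "n_query": r.n,
                "N_universe": r.N,
                "p": r.p_value,
                "bh_q": r.bh_q,
                "overlap": ";".join(r.overlap),
            }
            for r in results
        ],
        columns=[
            "set_name",
            "description",
            "k_overlap",
            "K_set_size",
            "n_query",
            "N_universe",
            "p",
            "bh_q",
            "overlap",
        ],
    )
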