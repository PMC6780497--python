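"""Supervised clustering of signature glycopeptides.

Rows (glycopeptides) are z-scored and clustered hierarchically with
1 - Pearson correlation distance and average linkage; columns are NOT
clustered but kept in the fixed supervised order (non-type channel block
first, then the luminal/basal block, each channel's replicates together).
The agglomeration is deterministic: scipy's linkage breaks distance ties
by cluster index, and leaf order follows a recursive smaller-subtree-first
traversal of the merge tree.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io_formats import SampleDesign
from .quantitation import AbundanceMatrix


@dataclasses.dataclass
class ClusterResult:
    row_order: list[str]  # leaf order, top to bottom
    column_order: list[tuple[int, str]]  # supervised: non-type block first
    linkage: np.ndarray  # scipy linkage matrix
    zscored: pd.DataFrame  # rows z-scored, columns in supervised order
    constant_rows: list[str]  # rows with zero variance, left at 0


def supervised_column_order(design: SampleDesign) -> list[tuple[int, str]]:
    return [
        (ch, rep)
        for ch in (*design.non_type_channels, *design.reference_channels)
        for rep in design.replicate_ids
    ]


def zscore_rows(data: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """(x - row mean) / row sd over finite values; sample sd by default.

    Constant rows (sd = 0) are set to 0 and flagged instead of producing
    infinities.
    """
    means = data.mean(axis=1, skipna=True)
    sds = data.std(axis=1, ddof=ddof, skipna=True)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    safe_sd = sds.replace(0, np.nan)
    z = data.sub(means, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = z.loc[constant].where(data.loc[constant].isna(), 0.0)
    return z, constant


def _pearson_distance(data: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distances over pairwise-complete columns."""
    corr = data.transpose().corr(min_periods=2)
    bad_pairs = []
    n = len(data)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(corr.iat[i, j]):
                bad_pairs.append((data.index[i], data.index[j]))
    if bad_pairs:
        raise ValueError(
            "rows share fewer than 2 finite columns or have zero variance: "
            + "; ".join(f"{a} / {b}" for a, b in bad_pairs[:5])
        )
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return squareform(dist, checks=False)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Recursive traversal, smaller subtree first; ties -> lower node id."""
    sizes = {i: 1 for i in range(n)}
    for idx, (a, b, _, size) in enumerate(Z):
        sizes[n + idx] = int(size)

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        first, second = (a, b) if (sizes[a], a) <= (sizes[b], b) else (b, a)
        return walk(first) + walk(second)

    return walk(n + len(Z) - 1) if len(Z) else list(range(n))


def hierarchical_cluster_rows(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    zscore: bool = True,
    method: str = "average",
) -> ClusterResult:
    """Cluster matrix rows with 1 - Pearson / average linkage.

    Requires >= 2 rows; rows must pairwise share >= 2 finite columns.
    """
    ordered_cols = [c for c in supervised_column_order(design) if c in matrix.data.columns]
    data = matrix.data.reindex(columns=ordered_cols)
    if len(data) < 2:
        raise ValueError("clustering needs at least 2 rows")
    z, constant = zscore_rows(data) if zscore else (data.copy(), [])
    # Pearson is shift/scale invariant, so distances come from the raw rows;
    # constant rows would have undefined correlation and are caught below.
    condensed = _pearson_distance(data)
    Z = scipy_linkage(condensed, method=method)
    order = _leaf_order(Z, len(data))
    return ClusterResult(
        row_order=[data.index[i] for i in order],
        column_order=ordered_cols,
        linkage=Z,
        zscored=z,
        constant_rows=constant,
    )


def cut_tree(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat cluster labels (1..k) for every row, from the linkage tree."""
    n = len(result.zscored)
    labels = fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.zscored.index, (int(x) for x in labels)))


def linkage_table(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        result.linkage,
        columns=["child_a", "child_b", "height", "size"],
    ).astype({"child_a": int, "child_b": int, "size": int})


def heatmap(result: ClusterResult, path: str) -> None:
    """Row-ordered z-score heatmap with the supervised column blocks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.zscored.reindex(index=result.row_order)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.04 * len(data) + 2)))
    im = ax.imshow(
        np.ma.masked_invalid(data.to_numpy()),
        aspect="auto",
        cmap="RdBu_r",
        vmin=-2.5,
        vmax=2.5,
        interpolation="nearest",
    )
    ax.set_xticks(range(len(result.column_order)))
    ax.set_xticklabels([f"{ch}/{rep}" for ch, rep in result.column_order], rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(data)} glycopeptides (leaf order)")
    fig.colorbar(im, ax=ax, label="row z-score", shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
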