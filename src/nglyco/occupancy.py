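"""Occupancy-quadrant integration of glyco and global-protein fold changes.

A glycopeptide's fold change can reflect either a change in glycosylation
site occupancy or a change in the abundance of its parent protein.  The
quadrant classification separates the two by comparing the glycopeptide
fold change against the protein fold change from the global-proteome
aliquot:

* ``occupancy_strong`` - glyco changed at the strong (2-fold) threshold on
  a protein that is unchanged (the blue quadrant points);
* ``glyco_changed`` - glyco changed at 1.5-fold, protein unchanged (yellow);
* ``concordant`` - both changed at 1.5-fold in the same direction (brown);
* ``discordant`` - both changed but in opposite directions (rare);
* ``unchanged`` - neither changed (grey);
* ``protein_NI`` - the protein was not identified in the global data.

Thresholds are applied symmetrically in log space (fc >= t or fc <= 1/t),
inclusively, and membership is defined by fold change alone; an alternative
protein-level count restricted to statistically significant glycopeptides
is reported alongside.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import LOG2_EPS


class Quadrant(str, enum.Enum):
    occupancy_strong = "occupancy_strong"
    glyco_changed = "glyco_changed"
    concordant = "concordant"
    discordant = "discordant"
    unchanged = "unchanged"
    protein_NI = "protein_NI"


#: Plot colours per quadrant, matching the conventional colouring.
QUADRANT_COLORS = {
    Quadrant.occupancy_strong: "#1f5fbf",  # blue
    Quadrant.glyco_changed: "#e6b800",  # yellow
    Quadrant.concordant: "#8b5a2b",  # brown
    Quadrant.discordant: "#c23b78",
    Quadrant.unchanged: "#9e9e9e",  # grey
}


def _changed(fc: float, threshold: float) -> bool:
    """fc beyond the threshold in either direction, inclusive in log2."""
    cut = math.log2(threshold)
    log2fc = math.log2(fc)
    return log2fc >= cut - LOG2_EPS or log2fc <= -cut + LOG2_EPS


def classify_occupancy(
    glyco_fc: float,
    protein_fc: float | None,
    t_glyco: float = 1.5,
    t_strong: float = 2.0,
) -> Quadrant:
    """Assign one (glycopeptide, protein) fold-change pair to a quadrant.

    ``protein_fc`` of None or NaN means the protein was not identified in
    the global-proteome data.  Fold changes must be positive.
    """
    if not np.isfinite(glyco_fc) or glyco_fc <= 0:
        raise ValueError(f"glyco fold change must be a positive real, got {glyco_fc!r}")
    if protein_fc is None or (isinstance(protein_fc, float) and np.isnan(protein_fc)):
        return Quadrant.protein_NI
    if not np.isfinite(protein_fc) or protein_fc <= 0:
        raise ValueError(f"protein fold change must be a positive real, got {protein_fc!r}")

    glyco_strong = _changed(glyco_fc, t_strong)
    glyco_mild = _changed(glyco_fc, t_glyco)
    protein_changed = _changed(protein_fc, t_glyco)

    if glyco_strong and not protein_changed:
        return Quadrant.occupancy_strong
    if glyco_mild and not protein_changed:
        return Quadrant.glyco_changed
    if glyco_mild and protein_changed:
        same_direction = (glyco_fc >= 1.0) == (protein_fc >= 1.0)
        return Quadrant.concordant if same_direction else Quadrant.discordant
    return Quadrant.unchanged


@dataclasses.dataclass
class OccupancySummary:
    n_calls: int
    n_dysregulated_glyco: int  # distinct glycopeptides changed at 1.5-fold
    n_occupancy_only_proteins: int
    n_occupancy_only_proteins_significant: int
    quadrant_counts: dict[str, int]


def integrate(
    glyco_differential: pd.DataFrame,
    protein_differential: pd.DataFrame,
    site_map: Mapping[str, set[str]],
    t_glyco: float = 1.5,
    t_strong: float = 2.0,
) -> tuple[pd.DataFrame, OccupancySummary]:
    """One occupancy call per (glycopeptide, claimed accession) pair.

    ``site_map`` maps glycopeptide entity ids to the accessions carrying
    their validated sites.  The occupancy-only protein set contains the
    accessions with at least one occupancy_strong or glyco_changed call and
    no concordant/discordant call; a second count restricts the contributing
    glycopeptides to the statistically significant ones.
    """
    protein_fc = dict(zip(protein_differential["entity"], protein_differential["fc"]))
    if "ni" in protein_differential.columns:
        protein_ni = dict(
            zip(protein_differential["entity"], protein_differential["ni"].astype(bool))
        )
    else:
        protein_ni = {}

    rows: list[dict] = []
    for rec in glyco_differential.itertuples(index=False):
        if not np.isfinite(rec.fc):
            continue  # glyco side NI: no call possible
        for accession in sorted(site_map.get(rec.entity, set())):
            p_fc = protein_fc.get(accession)
            if p_fc is not None and (protein_ni.get(accession, False) or not np.isfinite(p_fc)):
                p_fc = None
            quadrant = classify_occupancy(rec.fc, p_fc, t_glyco=t_glyco, t_strong=t_strong)
            rows.append(
                {
                    "glycopeptide": rec.entity,
                    "protein": accession,
                    "glyco_fc": rec.fc,
                    "glyco_log2fc": rec.log2fc,
                    "protein_fc": np.nan if p_fc is None else p_fc,
                    "protein_log2fc": np.nan if p_fc is None else math.log2(p_fc),
                    "quadrant": quadrant.value,
                    "glyco_significant": bool(getattr(rec, "significant", False)),
                }
            )
    calls = pd.DataFrame(
        rows,
        columns=[
            "glycopeptide",
            "protein",
            "glyco_fc",
            "glyco_log2fc",
            "protein_fc",
            "protein_log2fc",
            "quadrant",
            "glyco_significant",
        ],
    )

    occupancy_quadrants = {Quadrant.occupancy_strong.value, Quadrant.glyco_changed.value}
    conflict_quadrants = {Quadrant.concordant.value, Quadrant.discordant.value}

    def occupancy_only_proteins(subset: pd.DataFrame) -> set[str]:
        with_occ = set(subset.loc[subset["quadrant"].isin(occupancy_quadrants), "protein"])
        with_conflict = set(calls.loc[calls["quadrant"].isin(conflict_quadrants), "protein"])
        return with_occ - with_conflict

    dysregulated = {
        rec.entity
        for rec in glyco_differential.itertuples(index=False)
        if np.isfinite(rec.fc) and _changed(rec.fc, t_glyco)
    }

    quadrant_counts = {q.value: 0 for q in Quadrant}
    if len(calls):
        quadrant_counts.update(calls["quadrant"].value_counts().to_dict())

    summary = OccupancySummary(
        n_calls=int(len(calls)),
        n_dysregulated_glyco=len(dysregulated),
        n_occupancy_only_proteins=len(occupancy_only_proteins(calls)),
        n_occupancy_only_proteins_significant=len(
            occupancy_only_proteins(calls[calls["glyco_significant"].astype(bool)])
        ),
        quadrant_counts=quadrant_counts,
    )
    return calls, summary


def quadrant_plot(
    calls: pd.DataFrame,
    path: str,
    t_glyco: float = 1.5,
    t_strong: float = 2.0,
) -> pd.DataFrame:
    """Scatter of log2 glyco fc vs log2 protein fc with quadrant colouring.

    protein_NI calls carry no x-coordinate and are excluded from the plot
    (they remain in the calls table).  Returns the plotted point data,
    which is also written next to the image as ``<path>.data.tsv`` so the
    rendering can be tested without reading pixels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = calls[calls["quadrant"] != Quadrant.protein_NI.value].copy()
    plotted["color"] = [QUADRANT_COLORS[Quadrant(q)] for q in plotted["quadrant"]]

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(
        plotted["protein_log2fc"],
        plotted["glyco_log2fc"],
        c=plotted["color"],
        s=14,
        alpha=0.8,
        linewidths=0,
    )
    for cut in (math.log2(t_glyco), -math.log2(t_glyco)):
        ax.axvline(cut, color="0.7", lw=0.8, ls="--")
        ax.axhline(cut, color="0.7", lw=0.8, ls="--")
    for cut in (math.log2(t_strong), -math.log2(t_strong)):
        ax.axhline(cut, color="0.85", lw=0.8, ls=":")
    ax.set_xlabel("log2 protein fold change (non-type / luminal+basal)")
    ax.set_ylabel("log2 glycopeptide fold change")
    ax.set_title("Glycosylation occupancy vs protein abundance")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=color, label=q.value)
        for q, color in QUADRANT_COLORS.items()
    ]
    ax.legend(handles=handles, fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    data = plotted[["glycopeptide", "protein", "protein_log2fc", "glyco_log2fc", "quadrant", "color"]]
    data.to_csv(f"{path}.data.tsv", sep="\t", index=False, lineterminator="\n")
    return data
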