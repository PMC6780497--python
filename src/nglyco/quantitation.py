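"""TMT reporter quantitation: abundance matrices and group fold changes.

Reporter intensities are log2-transformed (zeros become missing), columns
are the 6 channels x R replicates, and columns are median-centred by
default under the equal-loading assumption of TMT.  The contrast fold
change is the ratio of geometric means: the difference of log2 means over
the non-type channels versus the luminal/basal channels, across all
replicates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glycosites import GlycopeptideRecord
from .io_formats import CHANNELS, SampleDesign
from .psm_filtering import PeptideQuantRecord

#: One matrix entry: (entity id, replicate id, channel -> raw intensity).
Entry = tuple[str, str, Mapping[int, float]]


@dataclasses.dataclass
class AbundanceMatrix:
    """Entities x (channel, replicate) of normalized log2 abundances."""

    data: pd.DataFrame  # columns: MultiIndex (channel, replicate)
    dataset_tag: str  # "glyco" or "global"

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_for(self, channels: Iterable[int], replicates: Iterable[str]) -> list[tuple[int, str]]:
        want = [(ch, rep) for ch in channels for rep in replicates]
        return [c for c in want if c in self.data.columns]


@dataclasses.dataclass
class FoldChangeRecord:
    """Non-type vs luminal/basal contrast for one entity.

    ``ni`` marks entities with no observation on one side (fold change not
    computable; "not identified" when the entity is absent altogether).
    """

    entity_id: str
    log2fc: float
    fc: float
    mean_non_type: float
    mean_reference: float
    n_non_type: int
    n_reference: int
    ni: bool = False


def glycopeptide_entries(glycopeptides: Iterable[GlycopeptideRecord]) -> list[Entry]:
    """One matrix entry per (glycopeptide entity, replicate)."""
    return [
        (g.entity_id, g.base.replicate_id, g.base.reporter_intensity) for g in glycopeptides
    ]


def rollup_protein(peptide_records: Iterable[PeptideQuantRecord]) -> list[Entry]:
    """Protein intensity = sum of its peptides' raw intensities, per column.

    Peptides shared between proteins contribute to every claimed accession
    (no razor-protein parsimony), consistent with the site-calling policy.
    """
    acc: dict[tuple[str, str], dict[int, float]] = {}
    for rec in peptide_records:
        for accession in rec.protein_accessions:
            key = (accession, rec.replicate_id)
            bucket = acc.setdefault(key, {ch: 0.0 for ch in CHANNELS})
            for ch in CHANNELS:
                bucket[ch] += rec.reporter_intensity[ch]
    return [(accession, rep, intensities) for (accession, rep), intensities in sorted(acc.items())]


def build_matrix(entries: Sequence[Entry], design: SampleDesign, dataset_tag: str) -> AbundanceMatrix:
    """Log2-transform raw intensities into an entity x column matrix.

    Zero intensities become missing.  A duplicate (entity, replicate) entry
    is an error: aggregation must happen upstream.
    """
    columns = pd.MultiIndex.from_tuples(
        [(ch, rep) for ch in CHANNELS for rep in design.replicate_ids],
        names=["channel", "replicate"],
    )
    seen: set[tuple[str, str]] = set()
    rows: dict[str, dict[tuple[int, str], float]] = {}
    for entity, replicate, intensities in entries:
        if (entity, replicate) in seen:
            raise ValueError(f"duplicate matrix entry for entity {entity!r}, replicate {replicate!r}")
        seen.add((entity, replicate))
        row = rows.setdefault(entity, {})
        for ch in CHANNELS:
            v = intensities.get(ch, 0.0)
            row[(ch, replicate)] = math.log2(v) if v > 0 else np.nan
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    df = df.sort_index()
    df.columns = columns
    return AbundanceMatrix(data=df, dataset_tag=dataset_tag)


def normalize_columns(matrix: AbundanceMatrix, mode: str = "median") -> AbundanceMatrix:
    """Median-centre every (channel, replicate) column in log2 space.

    ``mode="none"`` returns the matrix unchanged.  An all-missing column is
    an error naming the offending (channel, replicate).
    """
    if mode == "none":
        return AbundanceMatrix(data=matrix.data.copy(), dataset_tag=matrix.dataset_tag)
    if mode != "median":
        raise ValueError(f"unknown normalization mode {mode!r}")
    medians = matrix.data.median(axis=0, skipna=True)
    empty = medians[medians.isna()]
    if len(empty):
        ch, rep = empty.index[0]
        raise ValueError(f"column (channel={ch}, replicate={rep}) has no finite values")
    return AbundanceMatrix(data=matrix.data - medians, dataset_tag=matrix.dataset_tag)


def group_fold_change(row: pd.Series, design: SampleDesign, entity_id: str = "") -> FoldChangeRecord:
    """Fold change for one matrix row (a Series with (channel, replicate) index)."""
    nt_cols = [(ch, rep) for ch in design.non_type_channels for rep in design.replicate_ids]
    ref_cols = [(ch, rep) for ch in design.reference_channels for rep in design.replicate_ids]
    nt = row.reindex(nt_cols).dropna()
    ref = row.reindex(ref_cols).dropna()
    if len(nt) == 0 or len(ref) == 0:
        return FoldChangeRecord(
            entity_id=entity_id,
            log2fc=np.nan,
            fc=np.nan,
            mean_non_type=float(nt.mean()) if len(nt) else np.nan,
            mean_reference=float(ref.mean()) if len(ref) else np.nan,
            n_non_type=len(nt),
            n_reference=len(ref),
            ni=True,
        )
    log2fc = float(nt.mean() - ref.mean())
    return FoldChangeRecord(
        entity_id=entity_id,
        log2fc=log2fc,
        fc=float(2.0**log2fc),
        mean_non_type=float(nt.mean()),
        mean_reference=float(ref.mean()),
        n_non_type=len(nt),
        n_reference=len(ref),
    )


def fold_changes(matrix: AbundanceMatrix, design: SampleDesign) -> pd.DataFrame:
    """Vectorized :func:`group_fold_change` over all rows of a matrix."""
    nt_cols = [(ch, rep) for ch in design.non_type_channels for rep in design.replicate_ids]
    ref_cols = [(ch, rep) for ch in design.reference_channels for rep in design.replicate_ids]
    nt = matrix.data.reindex(columns=nt_cols)
    ref = matrix.data.reindex(columns=ref_cols)
    mean_nt = nt.mean(axis=1, skipna=True)
    mean_ref = ref.mean(axis=1, skipna=True)
    n_nt = nt.notna().sum(axis=1)
    n_ref = ref.notna().sum(axis=1)
    log2fc = (mean_nt - mean_ref).where((n_nt > 0) & (n_ref > 0))
    return pd.DataFrame(
        {
            "entity": matrix.data.index,
            "log2fc": log2fc.to_numpy(),
            "fc": np.power(2.0, log2fc.to_numpy()),
            "mean_non_type": mean_nt.to_numpy(),
            "mean_reference": mean_ref.to_numpy(),
            "n_non_type": n_nt.to_numpy(),
            "n_reference": n_ref.to_numpy(),
            "ni": ((n_nt == 0) | (n_ref == 0)).to_numpy(),
        }
    )


def matrix_to_frame(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Flatten for TSV output: columns named ``<channel>_<replicate>``."""
    flat = matrix.data.copy()
    flat.columns = [f"{ch}_{rep}" for ch, rep in matrix.data.columns]
    flat.insert(0, "entity", flat.index)
    return flat.reset_index(drop=True)


def frame_to_matrix(df: pd.DataFrame, dataset_tag: str) -> AbundanceMatrix:
    df = df.set_index("entity")
    cols = []
    for c in df.columns:
        ch, _, rep = str(c).partition("_")
        cols.append((int(ch), rep))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["channel", "replicate"])
    return AbundanceMatrix(data=df.astype(float), dataset_tag=dataset_tag)
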