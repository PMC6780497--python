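"""Target-decoy FDR control and PSM -> peptide aggregation.

The search engine scores every spectrum against targets and reversed decoys
in one concatenated database.  At a score threshold s the false-discovery
rate is estimated as #decoys(score >= s) / max(1, #targets(score >= s)); the
q-value of a PSM is the smallest estimated FDR over all thresholds at or
below its score.  The 1% FDR filter keeps targets with q <= 0.01, and
surviving PSMs are aggregated to peptide level by summing reporter-ion
intensities within (peptide, modifications, replicate) groups.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    CHANNELS,
    Modification,
    PsmRecord,
    canonical_modifications,
)


@dataclasses.dataclass(frozen=True)
class QValuedPsm:
    psm: PsmRecord
    q_value: float


@dataclasses.dataclass
class PeptideQuantRecord:
    """Peptide-level quantitation built from FDR-passing target PSMs."""

    peptide: str
    modifications: str  # canonical string, order-independent
    protein_accessions: tuple[str, ...]
    replicate_id: str
    reporter_intensity: dict[int, float]
    n_psms: int

    @property
    def parsed_modifications(self) -> tuple[tuple[int, Modification], ...]:
        out = []
        for tok in self.modifications.split(";"):
            if not tok:
                continue
            name, _, rest = tok.partition("(")
            out.append((int(rest[:-1]), Modification(name)))
        return tuple(out)


def compute_q_values(psms: Sequence[PsmRecord]) -> list[QValuedPsm]:
    """Assign target-decoy q-values by a threshold sweep over scores.

    Tied scores share one threshold; decoys receive the q of their score
    stratum.  Raises if the input contains no decoy (FDR inestimable) or no
    target.
    """
    n_targets_total = sum(not p.is_decoy for p in psms)
    n_decoys_total = len(psms) - n_targets_total
    if n_decoys_total == 0:
        raise ValueError("cannot estimate FDR: no decoy PSMs in input")
    if n_targets_total == 0:
        raise ValueError("cannot estimate FDR: no target PSMs in input")

    scores = np.array([p.score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    # unique thresholds, descending score
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoy[order]
    uniq, first_idx = np.unique(-s_sorted, return_index=True)
    thresholds = -uniq  # descending
    cum_decoys = np.cumsum(d_sorted)
    cum_targets = np.cumsum(~d_sorted)
    # counts at the last PSM of each threshold stratum
    last_idx = np.append(first_idx[1:], len(s_sorted)) - 1
    D = cum_decoys[last_idx]
    T = cum_targets[last_idx]
    fdr = np.minimum(1.0, D / np.maximum(1, T))  # an estimate above 1 is capped
    # q = running minimum of FDR-hat from the lowest score upward
    q_at_threshold = np.minimum.accumulate(fdr[::-1])[::-1]
    threshold_of = {s: q for s, q in zip(thresholds, q_at_threshold)}
    return [QValuedPsm(psm=p, q_value=float(threshold_of[p.score])) for p in psms]


def filter_fdr(qpsms: Iterable[QValuedPsm], alpha: float = 0.01) -> list[PsmRecord]:
    """Keep target PSMs with q <= alpha; decoys are always dropped."""
    return [qp.psm for qp in qpsms if not qp.psm.is_decoy and qp.q_value <= alpha]


def aggregate_psms(psms: Iterable[PsmRecord]) -> list[PeptideQuantRecord]:
    """Sum reporter intensities within (peptide, modifications, replicate).

    Protein accessions of group members are unioned, never treated as a
    conflict; ``n_psms`` records the group size.
    """
    groups: dict[tuple[str, str, str], list[PsmRecord]] = defaultdict(list)
    for p in psms:
        key = (p.peptide, canonical_modifications(p.modifications), p.replicate_id)
        groups[key].append(p)

    records = []
    for (peptide, mods, replicate), members in groups.items():
        intensities = {
            ch: float(sum(m.reporter_intensity[ch] for m in members)) for ch in CHANNELS
        }
        accessions = tuple(sorted({a for m in members for a in m.protein_accessions}))
        records.append(
            PeptideQuantRecord(
                peptide=peptide,
                modifications=mods,
                protein_accessions=accessions,
                replicate_id=replicate,
                reporter_intensity=intensities,
                n_psms=len(members),
            )
        )
    records.sort(key=lambda r: (r.peptide, r.modifications, r.replicate_id))
    return records
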