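"""Protein-centric N-glycosite calling from deamidated peptides.

PNGase F release of an N-glycan converts the glycosylated asparagine to
aspartate, which the search engine reports as a deamidation (+0.984 Da) on
N.  A deamidated N is accepted as a glycosite only if it sits in the
N-linked consensus sequon N-X-S/T (X any residue but proline), evaluated in
the context of the *protein* sequence: a peptide-terminal N can have its
S/T in the next tryptic peptide, so peptide-local validation would lose
true sites.  Deamidated N outside sequons are experimental artifacts
(spontaneous deamidation) and are logged and discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import Modification, ProteinRecord
from .psm_filtering import PeptideQuantRecord


@dataclasses.dataclass(frozen=True)
class GlycoSite:
    """One sequon-validated site: protein coordinates are 1-based."""

    protein_accession: str
    protein_position: int
    peptide_position: int
    sequon: str


@dataclasses.dataclass
class GlycopeptideRecord:
    """A sequon-validated deamidated peptide with its protein-mapped sites."""

    base: PeptideQuantRecord
    glyco_sites: tuple[GlycoSite, ...]
    ambiguous: bool = False  # peptide occurs more than once in some protein

    @property
    def peptide(self) -> str:
        return self.base.peptide

    @property
    def entity_id(self) -> str:
        """Unique glycopeptide key: sequence plus canonical modifications."""
        return f"{self.base.peptide}#{self.base.modifications}"

    @property
    def site_key(self) -> frozenset[tuple[str, int]]:
        return frozenset((s.protein_accession, s.protein_position) for s in self.glyco_sites)


@dataclasses.dataclass
class GlycositeRecord:
    protein_accession: str
    protein_position: int
    sequon: str
    supporting_peptides: set[str]


def find_deamidated_asn(record: PeptideQuantRecord) -> list[int]:
    """1-based peptide positions carrying deamidation_N, ascending.

    Q deamidation is chemistry noise for site calling and is ignored.
    """
    return sorted(
        pos for pos, mod in record.parsed_modifications if mod is Modification.deamidation_N
    )


def locate_peptide(peptide: str, protein_sequence: str) -> list[int]:
    """All 1-based start offsets of ``peptide`` in the protein (overlaps allowed)."""
    hits = []
    start = protein_sequence.find(peptide)
    while start != -1:
        hits.append(start + 1)
        start = protein_sequence.find(peptide, start + 1)
    return hits


def is_valid_sequon(protein_sequence: str, n_position: int) -> tuple[bool, str]:
    """Check N-X-S/T (X != P) at a 1-based position of the protein.

    Returns the validity flag and the (up to) 3-residue context string.
    """
    if not 1 <= n_position <= len(protein_sequence):
        raise ValueError(
            f"position {n_position} outside protein of length {len(protein_sequence)}"
        )
    window = protein_sequence[n_position - 1 : n_position + 2]
    ok = (
        len(window) == 3
        and window[0] == "N"
        and window[1] != "P"
        and window[2] in "ST"
    )
    return ok, window


def call_glycosites(
    peptide_records: Iterable[PeptideQuantRecord],
    proteome: Mapping[str, ProteinRecord],
) -> tuple[list[GlycopeptideRecord], list[GlycositeRecord], pd.DataFrame]:
    """Map deamidated-N peptides onto protein coordinates and validate sequons.

    A peptide is kept iff at least one deamidated N falls in a valid sequon
    of at least one claimed protein.  Returns the kept glycopeptides, the
    deduplicated per-protein site records, and a discard/artifact log with
    columns (peptide, modifications, replicate, reason, detail).
    """
    glycopeptides: list[GlycopeptideRecord] = []
    sites: dict[tuple[str, int], GlycositeRecord] = {}
    log_rows: list[dict] = []

    def log(rec: PeptideQuantRecord, reason: str, detail: str) -> None:
        log_rows.append(
            {
                "peptide": rec.peptide,
                "modifications": rec.modifications,
                "replicate": rec.replicate_id,
                "reason": reason,
                "detail": detail,
            }
        )

    for rec in peptide_records:
        deam_positions = find_deamidated_asn(rec)
        if not deam_positions:
            log(rec, "no_deamidated_asn", "")
            continue

        peptide_sites: list[GlycoSite] = []
        artifact_positions: set[tuple[str, int]] = set()
        found_anywhere = False
        ambiguous = False
        for acc in rec.protein_accessions:
            protein = proteome.get(acc)
            if protein is None:
                log(rec, "accession_not_in_fasta", acc)
                continue
            starts = locate_peptide(rec.peptide, protein.sequence)
            if not starts:
                continue
            found_anywhere = True
            if len(starts) > 1:
                ambiguous = True
            for start in starts:
                for pep_pos in deam_positions:
                    prot_pos = start + pep_pos - 1
                    ok, sequon = is_valid_sequon(protein.sequence, prot_pos)
                    if ok:
                        peptide_sites.append(
                            GlycoSite(
                                protein_accession=acc,
                                protein_position=prot_pos,
                                peptide_position=pep_pos,
                                sequon=sequon,
                            )
                        )
                    else:
                        artifact_positions.add((acc, prot_pos))

        if not found_anywhere:
            log(rec, "peptide_not_found_in_claimed_proteins", ";".join(rec.protein_accessions))
            continue
        for acc, prot_pos in sorted(artifact_positions):
            log(rec, "deamidation_outside_sequon", f"{acc}:{prot_pos}")
        if not peptide_sites:
            log(rec, "discarded_no_valid_sequon", "")
            continue

        unique_sites = tuple(sorted(set(peptide_sites), key=lambda s: (s.protein_accession, s.protein_position)))
        glycopeptides.append(
            GlycopeptideRecord(base=rec, glyco_sites=unique_sites, ambiguous=ambiguous)
        )
        for site in unique_sites:
            key = (site.protein_accession, site.protein_position)
            existing = sites.get(key)
            if existing is None:
                sites[key] = GlycositeRecord(
                    protein_accession=site.protein_accession,
                    protein_position=site.protein_position,
                    sequon=site.sequon,
                    supporting_peptides={rec.peptide},
                )
            else:
                existing.supporting_peptides.add(rec.peptide)

    site_records = [sites[k] for k in sorted(sites)]
    log_df = pd.DataFrame(
        log_rows, columns=["peptide", "modifications", "replicate", "reason", "detail"]
    )
    return glycopeptides, site_records, log_df


def count_unique(glycopeptides: Sequence[GlycopeptideRecord]) -> tuple[int, int]:
    """Unique glycopeptides (sequence + site set) and glycoproteins.

    Invariant to record order and to replicate multiplicity.
    """
    peptide_keys = {(g.peptide, g.site_key) for g in glycopeptides}
    proteins = {s.protein_accession for g in glycopeptides for s in g.glyco_sites}
    return len(peptide_keys), len(proteins)


def sites_table(site_records: Sequence[GlycositeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": s.protein_accession,
                "position": s.protein_position,
                "sequon": s.sequon,
                "n_supporting_peptides": len(s.supporting_peptides),
                "supporting_peptides": ";".join(sorted(s.supporting_peptides)),
            }
            for s in site_records
        ],
        columns=["protein", "position", "sequon", "n_supporting_peptides", "supporting_peptides"],
    )
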