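"""Readers and writers for every external format the pipeline touches.

No science lives here: FASTA proteomes, delimited PSM (peptide-spectrum
match) exports, GMT gene-set files, the TMT sample-design file and plain
TSV tables.  One canonical TSV dialect is defined for PSM tables, with a
configurable column map so other search-engine exports can be adapted.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

#: TMT 6-plex reporter channels, low to high mass.
CHANNELS: tuple[int, ...] = (126, 127, 128, 129, 130, 131)

#: Residues accepted in a protein sequence: the 20 standard amino acids
#: plus X (unknown), U (selenocysteine) and the B/Z ambiguity codes.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XUBZ")

SUBTYPES = ("luminal", "basal", "non_type")


class Modification(str, enum.Enum):
    """Canonical peptide modification names used throughout the pipeline."""

    deamidation_N = "deamidation_N"
    deamidation_Q = "deamidation_Q"
    carbamidomethyl_C = "carbamidomethyl_C"
    oxidation_M = "oxidation_M"
    TMT6_Nterm = "TMT6_Nterm"
    TMT6_K = "TMT6_K"


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry; accession is the first whitespace-delimited token."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.accession!r} contains invalid residues: "
                f"{''.join(sorted(bad))}"
            )


@dataclasses.dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from a search-engine export.

    ``modifications`` holds ``(position, Modification)`` pairs; positions are
    1-based indices into the bare peptide, with 0 denoting the N-terminus.
    ``reporter_intensity`` always carries all six TMT channels; a missing
    reporter ion is stored as 0 and excluded from log-space statistics later.
    """

    spectrum_id: str
    replicate_id: str
    peptide: str
    modifications: tuple[tuple[int, Modification], ...]
    protein_accessions: tuple[str, ...]
    score: float
    is_decoy: bool
    reporter_intensity: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.peptide or self.peptide != self.peptide.upper():
            raise ValueError(f"bad peptide sequence {self.peptide!r}")
        if not self.protein_accessions:
            raise ValueError(f"PSM {self.spectrum_id}: no protein accession")
        for pos, mod in self.modifications:
            if pos > len(self.peptide) or pos < 0:
                raise ValueError(
                    f"PSM {self.spectrum_id}: modification position {pos} outside "
                    f"peptide of length {len(self.peptide)}"
                )
            if mod is Modification.deamidation_N and self.peptide[pos - 1] != "N":
                raise ValueError(
                    f"PSM {self.spectrum_id}: deamidation_N at non-N position {pos}"
                )
            if mod is Modification.deamidation_Q and self.peptide[pos - 1] != "Q":
                raise ValueError(
                    f"PSM {self.spectrum_id}: deamidation_Q at non-Q position {pos}"
                )
        missing = set(CHANNELS) - set(self.reporter_intensity)
        if missing:
            raise ValueError(f"PSM {self.spectrum_id}: channels missing {missing}")
        if any(v < 0 for v in self.reporter_intensity.values()):
            raise ValueError(f"PSM {self.spectrum_id}: negative reporter intensity")


def canonical_modifications(
    modifications: Iterable[tuple[int, Modification]],
) -> str:
    """Order-independent string form, e.g. ``"TMT6_Nterm(0);deamidation_N(3)"``."""
    parts = sorted(modifications, key=lambda pm: (pm[0], pm[1].value))
    return ";".join(f"{mod.value}({pos})" for pos, mod in parts)


@dataclasses.dataclass
class SampleDesign:
    """TMT channel -> cell line -> subtype mapping plus the replicate labels.

    The contrast is always non_type versus the pooled luminal/basal reference.
    """

    channel_to_cell_line: dict[int, str]
    cell_line_to_subtype: dict[str, str]
    replicate_ids: list[str]

    def __post_init__(self) -> None:
        if sorted(self.channel_to_cell_line) != sorted(CHANNELS):
            raise ValueError("design must map exactly the six TMT channels")
        lines = list(self.channel_to_cell_line.values())
        if len(set(lines)) != len(lines):
            raise ValueError("channel -> cell line mapping must be a bijection")
        for line in lines:
            sub = self.cell_line_to_subtype.get(line)
            if sub not in SUBTYPES:
                raise ValueError(f"cell line {line!r} has invalid subtype {sub!r}")
        if not self.non_type_channels or not self.reference_channels:
            raise ValueError("both contrast groups must be non-empty")
        if not self.replicate_ids:
            raise ValueError("at least one replicate id required")

    def _channels_for(self, subtypes: set[str]) -> tuple[int, ...]:
        return tuple(
            ch
            for ch in CHANNELS
            if self.cell_line_to_subtype[self.channel_to_cell_line[ch]] in subtypes
        )

    @property
    def non_type_channels(self) -> tuple[int, ...]:
        return self._channels_for({"non_type"})

    @property
    def reference_channels(self) -> tuple[int, ...]:
        """Channels of the pooled luminal/basal reference group."""
        return self._channels_for({"luminal", "basal"})


def default_design(n_replicates: int = 4) -> SampleDesign:
    """The six bladder-carcinoma cell lines on TMT 126-131.

    T24, J82 and UMUC3 form the mesenchymal-like non-type group; RT112 and
    SW780 are luminal and VMCUB-1 basal, pooled as the reference group.
    """
    return SampleDesign(
        channel_to_cell_line={
            126: "T24",
            127: "J82",
            128: "RT112",
            129: "VMCUB-1",
            130: "UMUC3",
            131: "SW780",
        },
        cell_line_to_subtype={
            "T24": "non_type",
            "J82": "non_type",
            "UMUC3": "non_type",
            "RT112": "luminal",
            "SW780": "luminal",
            "VMCUB-1": "basal",
        },
        replicate_ids=[f"R{i}" for i in range(1, n_replicates + 1)],
    )


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT): set name -> (description, member symbols)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records, preserving file order.

    Raises on duplicate accessions and empty sequences.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession!r}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                description=entry.description[len(entry.id) :].strip(),
                sequence=str(entry.seq).upper(),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def index_proteome(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.accession: rec for rec in records}


# ---------------------------------------------------------------------------
# PSM tables

PSM_COLUMNS = (
    "spectrum_id",
    "replicate",
    "peptide",
    "modifications",
    "proteins",
    "score",
    "decoy",
    *(f"i{ch}" for ch in CHANNELS),
)

#: Search-engine modification labels -> canonical names.  "Deamidated" is
#: resolved by the residue at its position (N or Q); "TMT6plex" by position
#: (0 = peptide N-terminus, otherwise a lysine).
DEFAULT_MOD_NAMES: dict[str, str] = {
    "Deamidated": "deamidation",
    "Carbamidomethyl": "carbamidomethyl_C",
    "Oxidation": "oxidation_M",
    "TMT6plex": "TMT6",
}


@dataclasses.dataclass
class PsmTableDialect:
    """Column map and modification-string grammar for a PSM export.

    Modifications are written ``Name(position)`` and semicolon-separated.
    ``decoy_column`` may be None, in which case a decoy is recognised by
    ``decoy_prefix`` on every protein accession.
    """

    columns: dict[str, str] = dataclasses.field(
        default_factory=lambda: {c: c for c in PSM_COLUMNS}
    )
    mod_names: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MOD_NAMES)
    )
    decoy_column: str | None = "decoy"
    decoy_prefix: str = "XXX_"
    protein_separator: str = ";"


def _parse_modification(token: str, peptide: str, dialect: PsmTableDialect) -> tuple[int, Modification]:
    token = token.strip()
    if "(" not in token or not token.endswith(")"):
        raise ValueError(f"malformed modification token {token!r}")
    name, _, rest = token.partition("(")
    pos = int(rest[:-1])
    canonical = {m.value for m in Modification}
    if name in canonical:
        resolved = name
    elif name in dialect.mod_names:
        base = dialect.mod_names[name]
        if base == "deamidation":
            residue = peptide[pos - 1] if 1 <= pos <= len(peptide) else "?"
            if residue == "N":
                resolved = "deamidation_N"
            elif residue == "Q":
                resolved = "deamidation_Q"
            else:
                raise ValueError(
                    f"Deamidated({pos}) sits on residue {residue!r}, expected N or Q"
                )
        elif base == "TMT6":
            resolved = "TMT6_Nterm" if pos == 0 else "TMT6_K"
        else:
            resolved = base
    else:
        raise ValueError(f"unknown modification name {name!r}")
    return pos, Modification(resolved)


def read_psm_table(path: str | Path, dialect: PsmTableDialect | None = None) -> list[PsmRecord]:
    """Parse a delimited PSM export into :class:`PsmRecord` objects.

    Blank intensity cells become 0; the decoy flag comes from the configured
    boolean column or, failing that, from an accession prefix.
    """
    dialect = dialect or PsmTableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = dialect.columns
    required = [c for c in PSM_COLUMNS if c != "decoy"]
    missing = [c for c in required if colmap.get(c, c) not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks required columns: {missing}")

    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        get = lambda c: row_d[colmap.get(c, c)]
        peptide = get("peptide").strip().upper()
        mods_cell = get("modifications").strip()
        mods = tuple(
            _parse_modification(tok, peptide, dialect)
            for tok in mods_cell.split(";")
            if tok.strip()
        )
        accessions = tuple(
            a.strip() for a in get("proteins").split(dialect.protein_separator) if a.strip()
        )
        if dialect.decoy_column and colmap.get("decoy", dialect.decoy_column) in df.columns:
            is_decoy = str(row_d[colmap.get("decoy", dialect.decoy_column)]).strip().lower() in (
                "1", "true", "yes",
            )
        else:
            is_decoy = all(a.startswith(dialect.decoy_prefix) for a in accessions)
        intensities = {}
        for ch in CHANNELS:
            cell = get(f"i{ch}").strip()
            intensities[ch] = float(cell) if cell else 0.0
        records.append(
            PsmRecord(
                spectrum_id=get("spectrum_id"),
                replicate_id=get("replicate"),
                peptide=peptide,
                modifications=mods,
                protein_accessions=accessions,
                score=float(get("score")),
                is_decoy=is_decoy,
                reporter_intensity=intensities,
            )
        )
    return records


def write_psm_table(records: Sequence[PsmRecord], path: str | Path) -> None:
    """Write PSMs in the canonical TSV dialect (lossless round trip)."""
    rows = []
    for r in records:
        row = {
            "spectrum_id": r.spectrum_id,
            "replicate": r.replicate_id,
            "peptide": r.peptide,
            "modifications": canonical_modifications(r.modifications),
            "proteins": ";".join(r.protein_accessions),
            "score": repr(r.score),
            "decoy": "1" if r.is_decoy else "0",
        }
        for ch in CHANNELS:
            v = r.reporter_intensity[ch]
            row[f"i{ch}"] = "" if v == 0 else repr(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(PSM_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file; members are deduplicated, case kept."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *members = fields
            unique = tuple(dict.fromkeys(m for m in members if m))
            if not unique:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (description, unique)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# Generic tables and the design file


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with header, UTF-8, '.' decimal; missing values as literal NA."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def read_design(path: str | Path) -> SampleDesign:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SampleDesign(
        channel_to_cell_line={int(k): v for k, v in raw["channels"].items()},
        cell_line_to_subtype=dict(raw["subtypes"]),
        replicate_ids=list(raw["replicates"]),
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    payload = {
        "channels": {int(k): v for k, v in design.channel_to_cell_line.items()},
        "subtypes": dict(design.cell_line_to_subtype),
        "replicates": list(design.replicate_ids),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
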