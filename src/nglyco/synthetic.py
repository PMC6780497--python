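"""Synthetic study generator with known ground truth.

Everything the pipeline consumes can be generated here: a protein FASTA
(with reversed-sequence decoys), glyco and global PSM tables, the TMT
sample design and a GMT gene-set file.  The generator emulates the study
layout - six TMT channels carrying three non-type and three luminal/basal
cell lines, four replicates, a glyco aliquot of deamidated sequon peptides
plus artifact deamidation outside sequons, and a global-proteome aliquot -
with planted per-protein effect classes:

* ``concordant_up`` / ``concordant_down`` - glycosylation and protein
  abundance change together;
* ``occupancy_only_up`` / ``occupancy_only_down`` - glycosylation changes
  while protein abundance stays flat (the occupancy signal);
* ``null`` - no change on either axis.

Proteins are assembled from unique tryptic units (no internal K/R, K/R at
the end, never followed by P) so that in-silico digestion recovers exactly
the peptides the tables contain and every planted site has a known protein
coordinate.  Reporter values follow a log-normal model: per-peptide base
log2 abundance N(20, 1.5), the planted log2 fold change added to non-type
channels, a per-replicate shift N(0, 0.1) shared by all six channels of a
replicate, and i.i.d. channel noise N(0, noise_sd).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .io_formats import (
    CHANNELS,
    GeneSetCollection,
    Modification,
    ProteinRecord,
    PsmRecord,
    SampleDesign,
    canonical_modifications,
    default_design,
    write_design,
    write_fasta,
    write_gmt,
    write_psm_table,
)

EFFECT_CLASSES = (
    "concordant_up",
    "concordant_down",
    "occupancy_only_up",
    "occupancy_only_down",
    "null",
)

#: Residues used inside tryptic units: no K/R (cleavage control), P rare.
_INTERIOR = "ACDEFGHILMNQSTVWYP"
_INTERIOR_W = np.array([1.0] * 17 + [0.3])
_INTERIOR_W /= _INTERIOR_W.sum()


@dataclasses.dataclass
class SyntheticConfig:
    """Study-shaped generator settings; the seed is mandatory.

    Defaults mirror the emulated design: six channels, four replicates,
    2-fold planted effects, 0.25 log2 reporter noise, and a proteome of
    500 proteins of which 460 carry glycosites (1-4 each).
    """

    seed: int
    n_proteins: int = 500
    n_glyco_proteins: int = 460
    sites_per_protein: tuple[int, int] = (1, 4)
    units_per_protein: tuple[int, int] = (8, 20)
    unit_length: tuple[int, int] = (6, 20)
    class_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "concordant_up": 0.10,
            "concordant_down": 0.05,
            "occupancy_only_up": 0.10,
            "occupancy_only_down": 0.05,
            "null": 0.70,
        }
    )
    effect_size: float = 2.0  # fold change planted on affected proteins
    noise_sd: float = 0.25  # log2 reporter noise per (channel, replicate)
    replicate_sd: float = 0.10  # log2 shift shared by a replicate's channels
    base_mean: float = 20.0  # log2 peptide abundance
    base_sd: float = 1.5
    n_replicates: int = 4
    decoy_fraction: float = 0.2  # decoy PSM rows per target row
    artifact_rate: float = 0.05  # deamidated-N peptides outside sequons
    missing_rate: float = 0.02  # missing-at-random reporter dropout
    ni_protein_rate: float = 0.0  # glyco proteins absent from the global table
    global_peptides_per_protein: tuple[int, int] = (3, 8)
    target_score: tuple[float, float] = (8.0, 1.0)  # Normal(mean, sd)
    decoy_score: tuple[float, float] = (4.0, 1.0)

    def __post_init__(self) -> None:
        if set(self.class_proportions) != set(EFFECT_CLASSES):
            raise ValueError(f"class_proportions must cover exactly {EFFECT_CLASSES}")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for name in ("decoy_fraction", "artifact_rate", "missing_rate", "ni_protein_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_glyco_proteins > self.n_proteins:
            raise ValueError("n_glyco_proteins cannot exceed n_proteins")


@dataclasses.dataclass
class TruthGlycopeptide:
    peptide: str
    accession: str
    protein_positions: tuple[int, ...]  # 1-based N positions in the protein
    peptide_positions: tuple[int, ...]
    sequons: tuple[str, ...]
    is_artifact: bool
    entity_id: str  # peptide#canonical-mods, as the pipeline keys it


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    protein_class: dict[str, str]  # accession -> effect class (glyco proteins)
    glyco_fc: dict[str, float]
    protein_fc: dict[str, float]  # all target proteins
    glyco_sites: dict[str, list[tuple[int, str]]]  # accession -> [(pos, sequon)]
    glycopeptides: list[TruthGlycopeptide]
    ni_proteins: set[str]

    def non_null_entities(self) -> set[str]:
        return {
            g.entity_id
            for g in self.glycopeptides
            if not g.is_artifact and self.protein_class[g.accession] != "null"
        }

    def null_entities(self) -> set[str]:
        return {
            g.entity_id
            for g in self.glycopeptides
            if not g.is_artifact and self.protein_class[g.accession] == "null"
        }

    def occupancy_only_proteins(self) -> set[str]:
        return {
            acc
            for acc, cls in self.protein_class.items()
            if cls.startswith("occupancy_only")
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protein_class": self.protein_class,
            "glyco_fc": self.glyco_fc,
            "protein_fc": self.protein_fc,
            "glyco_sites": {k: [list(s) for s in v] for k, v in self.glyco_sites.items()},
            "glycopeptides": [dataclasses.asdict(g) for g in self.glycopeptides],
            "ni_proteins": sorted(self.ni_proteins),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            protein_class=raw["protein_class"],
            glyco_fc=raw["glyco_fc"],
            protein_fc=raw["protein_fc"],
            glyco_sites={k: [(int(p), s) for p, s in v] for k, v in raw["glyco_sites"].items()},
            glycopeptides=[
                TruthGlycopeptide(
                    peptide=g["peptide"],
                    accession=g["accession"],
                    protein_positions=tuple(g["protein_positions"]),
                    peptide_positions=tuple(g["peptide_positions"]),
                    sequons=tuple(g["sequons"]),
                    is_artifact=g["is_artifact"],
                    entity_id=g["entity_id"],
                )
                for g in raw["glycopeptides"]
            ],
            ni_proteins=set(raw["ni_proteins"]),
        )


# ---------------------------------------------------------------------------
# In-silico digestion (shared with tests as the ground-truth peptide model)


def digest_tryptic(
    sequence: str, max_missed: int = 2, min_length: int = 6, max_length: int = 40
) -> list[tuple[str, int, int]]:
    """Tryptic peptides as (peptide, 1-based start, n_missed_cleavages).

    Cleaves after K or R except when the next residue is P; emits every
    peptide with at most ``max_missed`` missed cleavages inside the length
    bounds.
    """
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    peptides: list[tuple[str, int, int]] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            pep = sequence[start:end]
            if min_length <= len(pep) <= max_length:
                peptides.append((pep, start + 1, j - i - 1))
    return peptides


# ---------------------------------------------------------------------------
# Proteome generation


def _random_unit(rng: np.random.Generator, length: int) -> str:
    """One tryptic unit: interior residues, then K or R; never starts with P."""
    body = rng.choice(list(_INTERIOR), size=length - 1, p=_INTERIOR_W)
    while body[0] == "P":  # P at unit start would suppress the upstream cleavage
        body[0] = rng.choice(list(_INTERIOR), p=_INTERIOR_W)
    return "".join(body) + rng.choice(["K", "R"])


def _plant_sequon(rng: np.random.Generator, unit: str) -> tuple[str, int, str]:
    """Overwrite an interior window with N-X-S/T (X not in P/K/R).

    Returns the new unit, the 1-based N position within it and the sequon.
    """
    pos = int(rng.integers(2, len(unit) - 3))  # 0-based; keep sequon internal
    x = rng.choice(list("ACDEFGHILMQSTVWY"))
    st = rng.choice(["S", "T"])
    new = unit[:pos] + "N" + x + st + unit[pos + 3 :]
    return new, pos + 1, f"N{x}{st}"


def _plant_artifact(rng: np.random.Generator, unit: str) -> tuple[str, int]:
    """Overwrite an interior window with N-P-A: a deamidated N that can
    never validate (X = P breaks the sequon in any protein context)."""
    pos = int(rng.integers(2, len(unit) - 3))
    new = unit[:pos] + "NPA" + unit[pos + 3 :]
    return new, pos + 1


def generate_proteome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord], SyntheticTruth]:
    """Random target proteins with planted sequons, plus reversed decoys.

    Returns (targets, decoys, truth); the truth's glycopeptide list is
    filled in later by :func:`generate_psm_tables` (sites are known here).
    """
    rng = rng or np.random.default_rng(config.seed)
    classes = rng.choice(
        EFFECT_CLASSES,
        size=config.n_glyco_proteins,
        p=[config.class_proportions[c] for c in EFFECT_CLASSES],
    )

    targets: list[ProteinRecord] = []
    truth = SyntheticTruth(
        protein_class={},
        glyco_fc={},
        protein_fc={},
        glyco_sites={},
        glycopeptides=[],
        ni_proteins=set(),
    )
    seen_units: set[str] = set()

    for idx in range(config.n_proteins):
        accession = f"SYNP{idx + 1:04d}"
        n_units = int(rng.integers(config.units_per_protein[0], config.units_per_protein[1] + 1))
        units = []
        for _ in range(n_units):
            while True:
                unit = _random_unit(rng, int(rng.integers(*config.unit_length)))
                if unit not in seen_units:
                    seen_units.add(unit)
                    units.append(unit)
                    break

        is_glyco = idx < config.n_glyco_proteins
        site_units: dict[int, tuple[int, str]] = {}
        if is_glyco:
            cls = str(classes[idx])
            n_sites = int(rng.integers(config.sites_per_protein[0], config.sites_per_protein[1] + 1))
            chosen = rng.choice(n_units, size=min(n_sites, n_units), replace=False)
            for u in sorted(int(c) for c in chosen):
                units[u], pos_in_unit, sequon = _plant_sequon(rng, units[u])
                site_units[u] = (pos_in_unit, sequon)
            effect = config.effect_size
            truth.protein_class[accession] = cls
            truth.glyco_fc[accession] = (
                effect if cls.endswith("_up") else 1.0 / effect if cls.endswith("_down") else 1.0
            )
            truth.protein_fc[accession] = (
                effect
                if cls == "concordant_up"
                else 1.0 / effect
                if cls == "concordant_down"
                else 1.0
            )
        else:
            truth.protein_fc[accession] = 1.0

        sequence = "".join(units)
        offsets = np.cumsum([0] + [len(u) for u in units[:-1]])
        sites = [
            (int(offsets[u]) + pos_in_unit, sequon)
            for u, (pos_in_unit, sequon) in sorted(site_units.items())
        ]
        if sites:
            truth.glyco_sites[accession] = sites
        targets.append(
            ProteinRecord(accession=accession, description=f"synthetic protein {idx + 1}", sequence=sequence)
        )

    if config.ni_protein_rate > 0 and truth.protein_class:
        glyco_accs = sorted(truth.protein_class)
        n_ni = int(round(config.ni_protein_rate * len(glyco_accs)))
        if n_ni:
            truth.ni_proteins = set(
                rng.choice(glyco_accs, size=n_ni, replace=False).tolist()
            )

    decoys = [
        ProteinRecord(
            accession=f"XXX_{t.accession}",
            description="reversed decoy",
            sequence=t.sequence[::-1],
        )
        for t in targets
    ]
    return targets, decoys, truth


# ---------------------------------------------------------------------------
# PSM tables


def _peptide_modifications(
    peptide: str, deamidated: Iterable[int] = ()
) -> tuple[tuple[int, Modification], ...]:
    mods: list[tuple[int, Modification]] = [(0, Modification.TMT6_Nterm)]
    for i, residue in enumerate(peptide, start=1):
        if residue == "K":
            mods.append((i, Modification.TMT6_K))
        elif residue == "C":
            mods.append((i, Modification.carbamidomethyl_C))
    mods.extend((int(p), Modification.deamidation_N) for p in deamidated)
    return tuple(sorted(mods, key=lambda pm: (pm[0], pm[1].value)))


def _reporter_values(
    rng: np.random.Generator,
    config: SyntheticConfig,
    design: SampleDesign,
    log2_fc: float,
) -> dict[str, dict[int, float]]:
    """Per-replicate channel intensities for one peptide."""
    base = rng.normal(config.base_mean, config.base_sd)
    nt = set(design.non_type_channels)
    out: dict[str, dict[int, float]] = {}
    for rep in design.replicate_ids:
        rep_shift = rng.normal(0.0, config.replicate_sd)
        row = {}
        for ch in CHANNELS:
            value = base + (log2_fc if ch in nt else 0.0) + rep_shift
            value += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            intensity = float(2.0**value)
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                intensity = 0.0
            row[ch] = intensity
        out[rep] = row
    return out


def _emit_psms(
    rng: np.random.Generator,
    config: SyntheticConfig,
    design: SampleDesign,
    tag: str,
    peptide: str,
    accession: str,
    log2_fc: float,
    deamidated: Iterable[int],
    counter: list[int],
) -> list[PsmRecord]:
    records = []
    values = _reporter_values(rng, config, design, log2_fc)
    mods = _peptide_modifications(peptide, deamidated)
    for rep in design.replicate_ids:
        counter[0] += 1
        records.append(
            PsmRecord(
                spectrum_id=f"{tag}.{counter[0]:06d}",
                replicate_id=rep,
                peptide=peptide,
                modifications=mods,
                protein_accessions=(accession,),
                score=float(rng.normal(*config.target_score)),
                is_decoy=False,
                reporter_intensity=values[rep],
            )
        )
    return records


def _emit_decoys(
    rng: np.random.Generator,
    config: SyntheticConfig,
    design: SampleDesign,
    tag: str,
    source_peptides: list[tuple[str, str]],
    n_rows: int,
    counter: list[int],
) -> list[PsmRecord]:
    records: list[PsmRecord] = []
    while len(records) < n_rows and source_peptides:
        pep, acc = source_peptides[int(rng.integers(len(source_peptides)))]
        decoy_pep = pep[:-1][::-1] + pep[-1]  # pseudo-reverse, keep tryptic terminus
        if decoy_pep == pep:  # palindromic body: no usable decoy form
            continue
        values = _reporter_values(rng, config, design, 0.0)
        mods = _peptide_modifications(decoy_pep)
        for rep in design.replicate_ids:
            counter[0] += 1
            records.append(
                PsmRecord(
                    spectrum_id=f"{tag}.{counter[0]:06d}",
                    replicate_id=rep,
                    peptide=decoy_pep,
                    modifications=mods,
                    protein_accessions=(f"XXX_{acc}",),
                    score=float(rng.normal(*config.decoy_score)),
                    is_decoy=True,
                    reporter_intensity=values[rep],
                )
            )
    return records[:n_rows]


def generate_psm_tables(
    config: SyntheticConfig,
    targets: list[ProteinRecord],
    truth: SyntheticTruth,
    design: SampleDesign | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[PsmRecord], list[PsmRecord], SampleDesign]:
    """Glyco-aliquot and global-aliquot PSMs with planted effects.

    Fills ``truth.glycopeptides`` (including artifact peptides) as a side
    effect so truth and tables stay mutually consistent.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    design = design or default_design(config.n_replicates)
    by_acc = {t.accession: t for t in targets}

    glyco_psms: list[PsmRecord] = []
    counter = [0]
    truth.glycopeptides = []
    glyco_source: list[tuple[str, str]] = []

    for accession, sites in sorted(truth.glyco_sites.items()):
        protein = by_acc[accession]
        log2_fc = float(np.log2(truth.glyco_fc[accession]))
        fully_cleaved = {
            (pep, start) for pep, start, missed in digest_tryptic(protein.sequence) if missed == 0
        }
        for prot_pos, sequon in sites:
            home = [
                (pep, start)
                for pep, start in fully_cleaved
                if start <= prot_pos < start + len(pep)
            ]
            assert len(home) == 1, "planted site must sit in exactly one tryptic unit"
            pep, start = home[0]
            pep_pos = prot_pos - start + 1
            glyco_psms.extend(
                _emit_psms(rng, config, design, "glyco", pep, accession, log2_fc, [pep_pos], counter)
            )
            glyco_source.append((pep, accession))
            truth.glycopeptides.append(
                TruthGlycopeptide(
                    peptide=pep,
                    accession=accession,
                    protein_positions=(prot_pos,),
                    peptide_positions=(pep_pos,),
                    sequons=(sequon,),
                    is_artifact=False,
                    entity_id=f"{pep}#{canonical_modifications(_peptide_modifications(pep, [pep_pos]))}",
                )
            )

    # artifact deamidation outside sequons: planted as extra peptides drawn
    # from non-glyco proteins, at a rate relative to the true glycopeptides
    n_artifacts = int(round(config.artifact_rate * len(truth.glycopeptides)))
    non_glyco_accs = [t.accession for t in targets if t.accession not in truth.glyco_sites]
    for i in range(n_artifacts):
        unit = _random_unit(rng, int(rng.integers(10, 18)))
        unit, pep_pos = _plant_artifact(rng, unit)
        host = non_glyco_accs[i % len(non_glyco_accs)] if non_glyco_accs else targets[0].accession
        protein = by_acc[host]
        # splice the artifact unit onto the protein end so it maps exactly
        new_seq = protein.sequence + unit
        by_acc[host] = ProteinRecord(host, protein.description, new_seq)
        prot_pos = len(protein.sequence) + pep_pos
        glyco_psms.extend(
            _emit_psms(rng, config, design, "glyco", unit, host, 0.0, [pep_pos], counter)
        )
        truth.glycopeptides.append(
            TruthGlycopeptide(
                peptide=unit,
                accession=host,
                protein_positions=(prot_pos,),
                peptide_positions=(pep_pos,),
                sequons=("NPA",),
                is_artifact=True,
                entity_id=f"{unit}#{canonical_modifications(_peptide_modifications(unit, [pep_pos]))}",
            )
        )
    targets[:] = [by_acc[t.accession] for t in targets]

    n_decoy_rows = int(round(config.decoy_fraction * len(glyco_psms)))
    if n_decoy_rows and glyco_source:
        glyco_psms.extend(
            _emit_decoys(rng, config, design, "glyco", glyco_source, n_decoy_rows, counter)
        )

    # global aliquot: non-glyco peptides of every protein outside the NI set
    global_psms: list[PsmRecord] = []
    counter_g = [0]
    global_source: list[tuple[str, str]] = []
    site_positions = {
        acc: {pos for pos, _ in sites} for acc, sites in truth.glyco_sites.items()
    }
    for protein in by_acc.values():
        accession = protein.accession
        if accession in truth.ni_proteins:
            continue
        log2_fc = float(np.log2(truth.protein_fc[accession]))
        candidates = [
            (pep, start)
            for pep, start, missed in digest_tryptic(protein.sequence)
            if missed == 0
            and not any(
                start <= pos < start + len(pep) for pos in site_positions.get(accession, ())
            )
        ]
        if not candidates:
            continue
        lo, hi = config.global_peptides_per_protein
        n_pick = min(int(rng.integers(lo, hi + 1)), len(candidates))
        picked = rng.choice(len(candidates), size=n_pick, replace=False)
        for c in sorted(int(x) for x in picked):
            pep, _ = candidates[c]
            global_psms.extend(
                _emit_psms(rng, config, design, "global", pep, accession, log2_fc, [], counter_g)
            )
            global_source.append((pep, accession))

    n_decoy_rows = int(round(config.decoy_fraction * len(global_psms)))
    if n_decoy_rows and global_source:
        global_psms.extend(
            _emit_decoys(rng, config, design, "global", global_source, n_decoy_rows, counter_g)
        )

    return glyco_psms, global_psms, design


def generate_gene_sets(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    n_random_sets: int = 10,
    random_set_size: tuple[int, int] = (20, 60),
) -> GeneSetCollection:
    """A planted-dysregulation set plus random sets over the glycoproteins.

    Synthetic accessions double as gene symbols, so enrichment of the
    planted set against a differential query is a known outcome.
    """
    glyco_accs = sorted(truth.protein_class)
    planted = sorted(acc for acc, cls in truth.protein_class.items() if cls != "null")
    sets = {}
    if planted:
        sets["PLANTED_DYSREGULATED"] = ("proteins with planted effects", tuple(planted))
    for i in range(n_random_sets):
        size = min(int(rng.integers(*random_set_size)), len(glyco_accs))
        members = tuple(sorted(rng.choice(glyco_accs, size=size, replace=False).tolist()))
        sets[f"RANDOM_SET_{i + 1:02d}"] = (f"random synthetic set {i + 1}", members)
    return GeneSetCollection(sets=sets)


def simulate_study(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete synthetic study into ``out_dir``.

    Writes proteome.fasta (targets + decoys), glyco_psms.tsv,
    global_psms.tsv, design.yaml, gene_sets.gmt and truth.json; returns the
    path of each.  Fully reproducible from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    targets, decoys, truth = generate_proteome(config, rng)
    glyco, global_, design = generate_psm_tables(config, targets, truth, rng=rng)
    gene_sets = generate_gene_sets(truth, rng)
    # regenerate decoys: artifact splicing may have extended some targets
    decoys = [
        ProteinRecord(f"XXX_{t.accession}", "reversed decoy", t.sequence[::-1]) for t in targets
    ]

    paths = {
        "fasta": out / "proteome.fasta",
        "glyco_psms": out / "glyco_psms.tsv",
        "global_psms": out / "global_psms.tsv",
        "design": out / "design.yaml",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_fasta([*targets, *decoys], paths["fasta"])
    write_psm_table(glyco, paths["glyco_psms"])
    write_psm_table(global_, paths["global_psms"])
    write_design(design, paths["design"])
    write_gmt(gene_sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
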