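"""End-to-end orchestration: filter -> call sites -> quantify -> test -> integrate.

`run_all` executes the full analysis on one study (glyco + global PSM
tables, FASTA, design, GMT) and writes every stage output plus a
``run_summary.json`` whose named fields are the pipeline's headline
counts: unique glycopeptides and glycoproteins, 1.5-fold dysregulated
glycopeptides, the significant signature (peptides/proteins and the
increased/decreased split), and the occupancy-only protein count.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .clustering import heatmap, hierarchical_cluster_rows, linkage_table
from .differential import run_differential, summarize_signature
from .enrichment import enrichment_table, run_ora
from .glycosites import call_glycosites, count_unique, sites_table
from .io_formats import (
    read_design,
    read_fasta,
    read_gmt,
    read_psm_table,
    index_proteome,
    write_table,
)
from .occupancy import integrate, quadrant_plot
from .psm_filtering import aggregate_psms, compute_q_values, filter_fdr
from .quantitation import (
    build_matrix,
    fold_changes,
    glycopeptide_entries,
    matrix_to_frame,
    normalize_columns,
    rollup_protein,
)

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    glyco_psms: str
    global_psms: str
    fasta: str
    design: str
    out_dir: str
    gene_sets: str | None = None
    fdr_alpha: float = 0.01
    p_alpha: float = 0.05
    fc_threshold: float = 1.5
    fc_strong: float = 2.0
    normalization: str = "median"
    permutation_test: bool = False
    n_permutations: int = 10000
    select_by_bh: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "p_alpha", "fc_threshold", "fc_strong"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str, log: list[dict], fn: Callable[[], Any], **counts: int) -> Any:
    try:
        result = fn()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with stage context
        raise PipelineError(name, str(exc)) from exc
    log.append({"stage": name, **counts})
    return result


def glycopeptide_table(glycopeptides) -> pd.DataFrame:
    rows = []
    for g in glycopeptides:
        row = {
            "entity": g.entity_id,
            "peptide": g.peptide,
            "modifications": g.base.modifications,
            "replicate": g.base.replicate_id,
            "n_psms": g.base.n_psms,
            "proteins": ";".join(g.base.protein_accessions),
            "glyco_sites": ";".join(
                f"{s.protein_accession}:{s.protein_position}:{s.sequon}" for s in g.glyco_sites
            ),
            "ambiguous": int(g.ambiguous),
        }
        for ch, v in g.base.reporter_intensity.items():
            row[f"i{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def site_map_from_glycopeptides(glycopeptides) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for g in glycopeptides:
        mapping.setdefault(g.entity_id, set()).update(
            s.protein_accession for s in g.glyco_sites
        )
    return mapping


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    for path_attr in ("glyco_psms", "global_psms", "fasta", "design"):
        p = getattr(config, path_attr)
        if not Path(p).is_file():
            raise PipelineError("inputs", f"missing input file for {path_attr}: {p}")
    if config.gene_sets and not Path(config.gene_sets).is_file():
        raise PipelineError("inputs", f"missing gene-set file: {config.gene_sets}")

    design = _stage("read_design", log, lambda: read_design(config.design))
    proteome = _stage(
        "read_fasta", log, lambda: index_proteome(read_fasta(config.fasta))
    )
    glyco_psms = _stage("read_glyco_psms", log, lambda: read_psm_table(config.glyco_psms))
    global_psms = _stage("read_global_psms", log, lambda: read_psm_table(config.global_psms))
    log[-2]["rows"] = len(glyco_psms)
    log[-1]["rows"] = len(global_psms)

    # --- FDR filtering, per aliquot
    def fdr_filter(psms):
        return filter_fdr(compute_q_values(psms), alpha=config.fdr_alpha)

    glyco_kept = _stage("fdr_glyco", log, lambda: fdr_filter(glyco_psms), rows_in=len(glyco_psms))
    log[-1]["rows_out"] = len(glyco_kept)
    global_kept = _stage(
        "fdr_global", log, lambda: fdr_filter(global_psms), rows_in=len(global_psms)
    )
    log[-1]["rows_out"] = len(global_kept)

    glyco_peptides = _stage("aggregate_glyco", log, lambda: aggregate_psms(glyco_kept))
    global_peptides = _stage("aggregate_global", log, lambda: aggregate_psms(global_kept))

    # --- glycosite calling
    glycopeptides, site_records, discard_log = _stage(
        "call_glycosites", log, lambda: call_glycosites(glyco_peptides, proteome)
    )
    n_unique_peptides, n_glycoproteins = count_unique(glycopeptides)
    log[-1].update(
        kept=len(glycopeptides),
        discarded=len(discard_log),
        unique_glycopeptides=n_unique_peptides,
        glycoproteins=n_glycoproteins,
    )
    write_table(glycopeptide_table(glycopeptides), out / "glycopeptides.tsv")
    write_table(sites_table(site_records), out / "glycosites.tsv")
    write_table(discard_log, out / "discard_log.tsv")

    # --- quantitation
    def quantify():
        glyco_matrix = normalize_columns(
            build_matrix(glycopeptide_entries(glycopeptides), design, "glyco"),
            mode=config.normalization,
        )
        global_matrix = normalize_columns(
            build_matrix(rollup_protein(global_peptides), design, "global"),
            mode=config.normalization,
        )
        return glyco_matrix, global_matrix

    glyco_matrix, global_matrix = _stage("quantify", log, quantify)
    log[-1].update(glyco_rows=len(glyco_matrix.data), global_rows=len(global_matrix.data))
    write_table(matrix_to_frame(glyco_matrix), out / "glyco_matrix.tsv")
    write_table(matrix_to_frame(global_matrix), out / "global_matrix.tsv")

    # --- differential, both datasets
    def diff(matrix):
        df = run_differential(
            matrix,
            design,
            fc_threshold=config.fc_threshold,
            alpha=config.p_alpha,
            permutation=config.permutation_test,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        if config.select_by_bh:
            df["significant"] = df["bh_q"].notna() & (df["bh_q"] <= config.p_alpha)
        return df

    glyco_diff = _stage("differential_glyco", log, lambda: diff(glyco_matrix))
    protein_diff = _stage("differential_global", log, lambda: diff(global_matrix))
    write_table(glyco_diff, out / "glyco_differential.tsv")
    write_table(protein_diff, out / "protein_differential.tsv")

    site_map = site_map_from_glycopeptides(glycopeptides)
    signature = summarize_signature(glyco_diff, site_map)

    # --- occupancy integration
    calls, occ_summary = _stage(
        "occupancy",
        log,
        lambda: integrate(
            glyco_diff,
            protein_diff,
            site_map,
            t_glyco=config.fc_threshold,
            t_strong=config.fc_strong,
        ),
    )
    log[-1].update(calls=occ_summary.n_calls)
    write_table(calls, out / "occupancy_calls.tsv")
    quadrant_plot(calls, str(out / "quadrant_plot.png"), config.fc_threshold, config.fc_strong)

    # --- significant-protein list (network-facing export) and enrichment
    signature_proteins = sorted(
        {
            acc
            for entity in glyco_diff.loc[glyco_diff["significant"].astype(bool), "entity"]
            for acc in site_map.get(entity, set())
        }
    )
    (out / "signature_proteins.txt").write_text(
        "\n".join(signature_proteins) + ("\n" if signature_proteins else ""), encoding="utf-8"
    )

    enrichment_rows = 0
    if config.gene_sets:
        def enrich():
            gene_sets = read_gmt(config.gene_sets)
            universe = sorted({acc for accs in site_map.values() for acc in accs})
            results, dropped = run_ora(signature_proteins, gene_sets, universe)
            return results, dropped

        results, dropped = _stage("enrichment", log, enrich)
        enrichment_rows = len(results)
        log[-1].update(sets_tested=len(results), query_dropped=len(dropped))
        write_table(enrichment_table(results), out / "enrichment.tsv")

    # --- supervised clustering of the signature
    sig_entities = glyco_diff.loc[glyco_diff["significant"].astype(bool), "entity"].tolist()
    clustered = 0
    if len(sig_entities) >= 2:
        def cluster():
            from .quantitation import AbundanceMatrix

            sub = AbundanceMatrix(
                data=glyco_matrix.data.loc[sig_entities], dataset_tag="glyco"
            )
            return hierarchical_cluster_rows(sub, design)

        result = _stage("clustering", log, cluster)
        clustered = len(result.row_order)
        write_table(
            pd.DataFrame({"entity": result.row_order, "leaf_rank": range(len(result.row_order))}),
            out / "cluster_row_order.tsv",
        )
        write_table(linkage_table(result), out / "cluster_linkage.tsv")
        heatmap(result, str(out / "signature_heatmap.png"))

    summary = {
        "schema_version": SCHEMA_VERSION,
        "nglyco_version": __version__,
        "n_unique_glycopeptides": n_unique_peptides,
        "n_glycoproteins": n_glycoproteins,
        "n_dysregulated_1p5": occ_summary.n_dysregulated_glyco,
        "n_signature_peptides": signature.n_significant_peptides,
        "n_signature_proteins": signature.n_proteins,
        "n_increased": signature.n_increased_1p5,
        "n_decreased": signature.n_decreased_1p5,
        "n_occupancy_only_proteins": occ_summary.n_occupancy_only_proteins,
        "n_occupancy_only_proteins_significant": occ_summary.n_occupancy_only_proteins_significant,
        "quadrant_counts": occ_summary.quadrant_counts,
        "n_clustered": clustered,
        "n_enriched_sets_tested": enrichment_rows,
        "replicates_treated_as_independent": True,
        "config": dataclasses.asdict(config),
        "stages": log,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1), encoding="utf-8")
    return summary
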