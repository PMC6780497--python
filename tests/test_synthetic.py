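"""Generator self-consistency: digestion, planted truth and reproducibility."""

import itertools

import numpy as np
import pytest

from nglyco.glycosites import is_valid_sequon
from nglyco.io_formats import read_psm_table
from nglyco.quantitation import build_matrix, fold_changes, glycopeptide_entries, normalize_columns
from nglyco.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    digest_tryptic,
    generate_proteome,
    simulate_study,
)


def brute_force_digest(sequence, max_missed, min_length, max_length):
    """Oracle: enumerate contiguous runs of fully-cleaved fragments."""
    cuts = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0, *cuts, len(sequence)]
    fragments = [
        (sequence[a:b], a + 1) for a, b in itertools.pairwise(bounds)
    ]
    out = set()
    for i in range(len(fragments)):
        for j in range(i, min(i + 1 + max_missed, len(fragments))):
            pep = "".join(f for f, _ in fragments[i : j + 1])
            if min_length <= len(pep) <= max_length:
                out.add((pep, fragments[i][1], j - i))
    return out


class TestDigestTryptic:
    def test_full_and_missed_cleavage_forms(self):
        got = set(digest_tryptic("AAKBBRCC", max_missed=2, min_length=2, max_length=10))
        assert got == {
            ("AAK", 1, 0),
            ("BBR", 4, 0),
            ("CC", 7, 0),
            ("AAKBBR", 1, 1),
            ("BBRCC", 4, 1),
            ("AAKBBRCC", 1, 2),
        }

    def test_kp_suppresses_cleavage(self):
        assert digest_tryptic("AAKPBB", min_length=2, max_length=10) == [("AAKPBB", 1, 0)]

    def test_no_cleavage_sites_returns_whole(self):
        assert digest_tryptic("ACDEFG", min_length=2, max_length=10) == [("ACDEFG", 1, 0)]
        assert digest_tryptic("ACDEFG", min_length=2, max_length=3) == []

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(4)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            seq = "".join(rng.choice(residues, size=rng.integers(10, 60)))
            got = set(digest_tryptic(seq, max_missed=2, min_length=2, max_length=50))
            assert got == brute_force_digest(seq, 2, 2, 50)


class TestGenerateProteome:
    def test_every_truth_site_is_a_valid_sequon(self):
        config = SyntheticConfig(seed=5, n_proteins=40, n_glyco_proteins=30)
        targets, decoys, truth = generate_proteome(config)
        by_acc = {t.accession: t for t in targets}
        assert truth.glyco_sites  # something was planted
        for accession, sites in truth.glyco_sites.items():
            for position, sequon in sites:
                ok, window = is_valid_sequon(by_acc[accession].sequence, position)
                assert ok and window == sequon

    def test_decoys_are_reversed_targets(self):
        config = SyntheticConfig(seed=5, n_proteins=10, n_glyco_proteins=5)
        targets, decoys, _ = generate_proteome(config)
        assert len(decoys) == len(targets)
        for t, d in zip(targets, decoys):
            assert d.accession == f"XXX_{t.accession}"
            assert d.sequence == t.sequence[::-1]

    def test_empty_proteome(self):
        config = SyntheticConfig(seed=1, n_proteins=0, n_glyco_proteins=0)
        targets, decoys, truth = generate_proteome(config)
        assert targets == [] and decoys == [] and truth.glyco_sites == {}

    def test_class_proportions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(
                seed=1,
                class_proportions={
                    "concordant_up": 0.5,
                    "concordant_down": 0.0,
                    "occupancy_only_up": 0.0,
                    "occupancy_only_down": 0.0,
                    "null": 0.4,
                },
            )


class TestSimulateStudy:
    def test_reproducible_from_seed(self, tmp_path):
        config = SyntheticConfig(seed=9, n_proteins=20, n_glyco_proteins=15)
        a = simulate_study(config, tmp_path / "a")
        b = simulate_study(config, tmp_path / "b")
        for key in ("fasta", "glyco_psms", "global_psms", "design", "gene_sets", "truth"):
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_truth_and_tables_mutually_consistent(self, small_study):
        _, paths, truth = small_study
        table_peptides = {
            (p.peptide, p.replicate_id) for p in read_psm_table(paths["glyco_psms"]) if not p.is_decoy
        }
        for g in truth.glycopeptides:
            assert (g.peptide, "R1") in table_peptides

    def test_ni_proteins_absent_from_global_table(self, small_study):
        _, paths, truth = small_study
        assert truth.ni_proteins
        global_accs = {
            acc
            for p in read_psm_table(paths["global_psms"])
            for acc in p.protein_accessions
        }
        assert not (truth.ni_proteins & global_accs)

    def test_decoy_fraction_approximate(self, small_study):
        config, paths, _ = small_study
        psms = read_psm_table(paths["glyco_psms"])
        n_decoy = sum(p.is_decoy for p in psms)
        n_target = len(psms) - n_decoy
        assert n_decoy == pytest.approx(config.decoy_fraction * n_target, rel=0.05)

    def test_truth_json_round_trip(self, small_study, tmp_path):
        _, paths, truth = small_study
        truth.to_json(tmp_path / "t.json")
        back = SyntheticTruth.from_json(tmp_path / "t.json")
        assert back.protein_class == truth.protein_class
        assert back.glyco_sites == truth.glyco_sites
        assert back.glycopeptides == truth.glycopeptides


class TestSamplingModel:
    def test_null_fold_change_spread_matches_closed_form(self, study42):
        """Empirical sd of log2fc over null rows ~= sigma * sqrt(1/12 + 1/12).

        The per-replicate shift is shared by all six channels of a replicate
        and cancels exactly in the group contrast, so only the channel noise
        contributes.
        """
        from nglyco.io_formats import index_proteome, read_design, read_fasta
        from nglyco.psm_filtering import aggregate_psms, compute_q_values, filter_fdr
        from nglyco.glycosites import call_glycosites

        config, paths, truth = study42
        design = read_design(paths["design"])
        kept = filter_fdr(compute_q_values(read_psm_table(paths["glyco_psms"])))
        gps, _, _ = call_glycosites(
            aggregate_psms(kept), index_proteome(read_fasta(paths["fasta"]))
        )
        matrix = normalize_columns(
            build_matrix(glycopeptide_entries(gps), design, "glyco"), mode="none"
        )
        fc = fold_changes(matrix, design).set_index("entity")
        null_entities = [e for e in truth.null_entities() if e in fc.index]
        assert len(null_entities) > 800
        spread = float(fc.loc[null_entities, "log2fc"].std())
        expected = config.noise_sd * np.sqrt(1 / 12 + 1 / 12)
        assert spread == pytest.approx(expected, rel=0.15)
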