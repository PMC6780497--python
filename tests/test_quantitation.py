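"""Abundance matrices, normalization contracts and fold-change arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nglyco.io_formats import CHANNELS, SampleDesign, default_design
from nglyco.quantitation import (
    build_matrix,
    fold_changes,
    frame_to_matrix,
    group_fold_change,
    matrix_to_frame,
    normalize_columns,
    rollup_protein,
)

from conftest import make_matrix, make_peptide_record


def swapped_design(design: SampleDesign) -> SampleDesign:
    """Same channels, contrast groups exchanged."""
    flip = {"non_type": "luminal", "luminal": "non_type", "basal": "non_type"}
    # map all reference lines to non_type and vice versa
    swapped = {
        line: ("non_type" if sub in ("luminal", "basal") else "luminal")
        for line, sub in design.cell_line_to_subtype.items()
    }
    return SampleDesign(design.channel_to_cell_line, swapped, design.replicate_ids)


class TestBuildMatrix:
    def test_log2_transform(self, design1):
        m = build_matrix([("e1", "R1", {ch: 8.0 for ch in CHANNELS})], design1, "glyco")
        assert m.data.loc["e1", (126, "R1")] == pytest.approx(3.0)

    def test_zero_becomes_missing(self, design1):
        intens = {ch: 8.0 for ch in CHANNELS}
        intens[131] = 0.0
        m = build_matrix([("e1", "R1", intens)], design1, "glyco")
        assert np.isnan(m.data.loc["e1", (131, "R1")])

    def test_column_count_is_channels_times_replicates(self):
        design = default_design(2)
        m = build_matrix([("e1", "R1", {ch: 4.0 for ch in CHANNELS})], design, "glyco")
        assert m.data.shape[1] == 12

    def test_duplicate_entry_rejected(self, design1):
        entries = [
            ("e1", "R1", {ch: 4.0 for ch in CHANNELS}),
            ("e1", "R1", {ch: 2.0 for ch in CHANNELS}),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(entries, design1, "glyco")

    def test_frame_round_trip(self, design4):
        rng = np.random.default_rng(1)
        m = make_matrix({f"e{i}": rng.normal(0, 1, 24) for i in range(5)}, design4)
        back = frame_to_matrix(matrix_to_frame(m), "glyco")
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)


class TestNormalizeColumns:
    def test_median_centering(self, design1):
        m = make_matrix({"a": [1, 0, 0, 0, 0, 0], "b": [2, 0, 0, 0, 0, 0], "c": [3, 0, 0, 0, 0, 0]}, design1)
        normalized = normalize_columns(m)
        assert normalized.data[(126, "R1")].tolist() == [-1.0, 0.0, 1.0]

    def test_median_zero_column_unchanged(self, design1):
        m = make_matrix({"a": [-1, 5, 5, 5, 5, 5], "b": [0, 5, 5, 5, 5, 5], "c": [1, 5, 5, 5, 5, 5]}, design1)
        normalized = normalize_columns(m)
        assert normalized.data[(126, "R1")].tolist() == [-1.0, 0.0, 1.0]

    def test_all_columns_median_zero_after_normalization(self, design4):
        rng = np.random.default_rng(7)
        m = make_matrix({f"e{i}": rng.normal(3, 2, 24) for i in range(40)}, design4)
        normalized = normalize_columns(m)
        medians = normalized.data.median(axis=0)
        assert np.allclose(medians.to_numpy(), 0.0, atol=1e-12)

    def test_all_missing_column_is_an_error(self, design1):
        m = make_matrix({"a": [np.nan, 1, 1, 1, 1, 1]}, design1)
        with pytest.raises(ValueError, match=r"channel=126"):
            normalize_columns(m)

    def test_none_mode_is_identity(self, design1):
        m = make_matrix({"a": [1, 2, 3, 4, 5, 6]}, design1)
        out = normalize_columns(m, mode="none")
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_affine_contract_row_differences_shifted_by_column_constants(self, design4):
        rng = np.random.default_rng(8)
        m = make_matrix({f"e{i}": rng.normal(0, 1, 24) for i in range(10)}, design4)
        normalized = normalize_columns(m)
        shift = m.data - normalized.data
        # the shift is a per-column constant, identical for every row
        assert np.allclose(shift.to_numpy(), shift.to_numpy()[0], atol=1e-12)


class TestRollupProtein:
    def test_peptides_summed_per_protein(self):
        records = [
            make_peptide_record("AAAGTK", "", accessions=("P1",), intensity=100.0),
            make_peptide_record("CCCGTK", "", accessions=("P1",), intensity=50.0),
        ]
        entries = rollup_protein(records)
        assert len(entries) == 1
        accession, replicate, intensities = entries[0]
        assert (accession, replicate) == ("P1", "R1")
        assert intensities[126] == 150.0

    def test_single_peptide_protein_equals_peptide(self):
        records = [make_peptide_record("AAAGTK", "", accessions=("P1",), intensity=42.0)]
        (_, _, intensities), = rollup_protein(records)
        assert all(intensities[ch] == 42.0 for ch in CHANNELS)

    def test_shared_peptide_contributes_to_each_protein(self):
        records = [make_peptide_record("AAAGTK", "", accessions=("P1", "P2"), intensity=10.0)]
        entries = rollup_protein(records)
        assert {e[0] for e in entries} == {"P1", "P2"}
        assert all(e[2][126] == 10.0 for e in entries)

    def test_protein_with_no_peptides_absent(self):
        assert rollup_protein([]) == []


class TestGroupFoldChange:
    def test_two_fold(self, design1):
        # non-type channels (126,127,130) at log2=3, reference at log2=2
        m = make_matrix({"e": [3, 3, 2, 2, 3, 2]}, design1)
        rec = group_fold_change(m.data.loc["e"], design1, "e")
        assert rec.fc == pytest.approx(2.0)

    def test_identical_groups_fc_one(self, design1):
        m = make_matrix({"e": [2, 2, 2, 2, 2, 2]}, design1)
        rec = group_fold_change(m.data.loc["e"], design1, "e")
        assert rec.fc == pytest.approx(1.0)
        assert rec.log2fc == pytest.approx(0.0)

    def test_four_fold_hand_computed(self, design1):
        # means: (4+4+4)/3 = 4 vs (2+2+2)/3 = 2 -> log2fc = 2 -> fc = 4
        m = make_matrix({"e": [4, 4, 2, 2, 4, 2]}, design1)
        rec = group_fold_change(m.data.loc["e"], design1, "e")
        assert rec.log2fc == pytest.approx(2.0)
        assert rec.fc == pytest.approx(4.0)

    def test_empty_side_flagged_ni(self, design1):
        m = make_matrix({"e": [np.nan, np.nan, 2, 2, np.nan, 2]}, design1)
        rec = group_fold_change(m.data.loc["e"], design1, "e")
        assert rec.ni and np.isnan(rec.fc)

    def test_antisymmetry_under_group_swap(self, design4):
        rng = np.random.default_rng(5)
        m = make_matrix({f"e{i}": rng.normal(0, 1, 24) for i in range(8)}, design4)
        fwd = fold_changes(m, design4)
        rev = fold_changes(m, swapped_design(design4))
        assert np.allclose(fwd["fc"].to_numpy() * rev["fc"].to_numpy(), 1.0)

    @given(shift=st.floats(-5, 5))
    def test_row_constant_leaves_fc_unchanged(self, shift):
        design = default_design(1)
        m = make_matrix({"e": [3.0, 2.5, 2.0, 1.0, 3.5, 1.5]}, design)
        base = group_fold_change(m.data.loc["e"], design, "e").fc
        shifted = group_fold_change(m.data.loc["e"] + shift, design, "e").fc
        assert shifted == pytest.approx(base)

    def test_vectorized_matches_scalar(self, design4):
        rng = np.random.default_rng(9)
        rows = {f"e{i}": rng.normal(0, 1, 24) for i in range(6)}
        m = make_matrix(rows, design4)
        table = fold_changes(m, design4).set_index("entity")
        for entity in rows:
            rec = group_fold_change(m.data.loc[entity], design4, entity)
            assert table.loc[entity, "fc"] == pytest.approx(rec.fc)
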