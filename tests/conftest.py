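"""Shared fixtures: synthetic studies at several scales and record builders."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nglyco.io_formats import CHANNELS, Modification, PsmRecord, SampleDesign, default_design
from nglyco.psm_filtering import PeptideQuantRecord
from nglyco.quantitation import AbundanceMatrix
from nglyco.synthetic import SyntheticConfig, SyntheticTruth, simulate_study

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


def make_psm(
    spectrum_id: str = "s1",
    score: float = 10.0,
    decoy: bool = False,
    peptide: str = "LKNGSR",
    mods: Sequence[tuple[int, Modification]] = (),
    replicate: str = "R1",
    accessions: Sequence[str] = ("P1",),
    intensity: Mapping[int, float] | float = 100.0,
) -> PsmRecord:
    if isinstance(intensity, (int, float)):
        intensity = {ch: float(intensity) for ch in CHANNELS}
    return PsmRecord(
        spectrum_id=spectrum_id,
        replicate_id=replicate,
        peptide=peptide,
        modifications=tuple(mods),
        protein_accessions=tuple(accessions),
        score=score,
        is_decoy=decoy,
        reporter_intensity=dict(intensity),
    )


def make_peptide_record(
    peptide: str = "LKNGSR",
    mods: str = "deamidation_N(3)",
    accessions: Sequence[str] = ("P1",),
    replicate: str = "R1",
    intensity: Mapping[int, float] | float = 100.0,
    n_psms: int = 1,
) -> PeptideQuantRecord:
    if isinstance(intensity, (int, float)):
        intensity = {ch: float(intensity) for ch in CHANNELS}
    return PeptideQuantRecord(
        peptide=peptide,
        modifications=mods,
        protein_accessions=tuple(accessions),
        replicate_id=replicate,
        reporter_intensity=dict(intensity),
        n_psms=n_psms,
    )


def make_matrix(
    rows: Mapping[str, Sequence[float]], design: SampleDesign, tag: str = "glyco"
) -> AbundanceMatrix:
    """Rows list log2 values channel-major: all replicates of 126, then 127, ..."""
    cols = pd.MultiIndex.from_tuples(
        [(ch, rep) for ch in CHANNELS for rep in design.replicate_ids],
        names=["channel", "replicate"],
    )
    df = pd.DataFrame.from_dict(dict(rows), orient="index").astype(float)
    df.columns = cols
    return AbundanceMatrix(data=df, dataset_tag=tag)


@pytest.fixture()
def design1() -> SampleDesign:
    """Single-replicate design: 6 columns, non-type = 126/127/130."""
    return default_design(n_replicates=1)


@pytest.fixture()
def design4() -> SampleDesign:
    return default_design(n_replicates=4)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """60-protein study with NI proteins and artifacts, for fast end-to-end tests."""
    config = SyntheticConfig(
        seed=11, n_proteins=60, n_glyco_proteins=40, ni_protein_rate=0.15
    )
    paths = simulate_study(config, tmp_path_factory.mktemp("small_study"))
    return config, paths, SyntheticTruth.from_json(paths["truth"])


@pytest.fixture(scope="session")
def study42(tmp_path_factory):
    """Seed-42 study at the ~2000-glycopeptide scale used for recovery checks."""
    config = SyntheticConfig(seed=42, n_proteins=900, n_glyco_proteins=800)
    paths = simulate_study(config, tmp_path_factory.mktemp("study42"))
    return config, paths, SyntheticTruth.from_json(paths["truth"])
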