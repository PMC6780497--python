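"""Welch t-tests and 1.5-fold classification of the non-type contrast.

Each matrix row is tested with a two-sample t-test with unequal variances
(Welch) on the per-(channel, replicate) log2 values, non-type versus
luminal/basal.  Direction is assigned from the fold change alone at an
inclusive 1.5-fold threshold; significance uses the raw p-value at 0.05,
with Benjamini-Hochberg q-values reported alongside.  A seeded label-
permutation p-value is available as a non-parametric alternative.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleDesign
from .quantitation import AbundanceMatrix, fold_changes

#: Guard against float rounding at the fold-change boundary (log2 scale).
LOG2_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float | None  # None = untestable (n < 2 on a side)


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sample t-test with unequal variances (Welch-Satterthwaite df).

    With n < 2 on either side the result is flagged untestable (p is None)
    rather than silently p = 1.  If both sample variances are zero and the
    means differ, t is +/-inf and p is reported as 0.0 (documented cap).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return WelchResult(t=np.nan, df=np.nan, p=None)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    diff = a.mean() - b.mean()
    se2 = va + vb
    if se2 == 0.0:
        if diff == 0.0:
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        return WelchResult(t=math.copysign(math.inf, diff), df=np.nan, p=0.0)
    t = diff / math.sqrt(se2)
    df = se2**2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))


def classify_direction(fc: float, fc_threshold: float = 1.5) -> str:
    """increased / decreased / unchanged at an inclusive, log-symmetric threshold."""
    if not np.isfinite(fc) or fc <= 0:
        return "unchanged"
    log2fc = math.log2(fc)
    cut = math.log2(fc_threshold)
    if log2fc >= cut - LOG2_EPS:
        return "increased"
    if log2fc <= -cut + LOG2_EPS:
        return "decreased"
    return "unchanged"


def _group_arrays(matrix: AbundanceMatrix, design: SampleDesign) -> tuple[np.ndarray, np.ndarray]:
    nt_cols = [(ch, rep) for ch in design.non_type_channels for rep in design.replicate_ids]
    ref_cols = [(ch, rep) for ch in design.reference_channels for rep in design.replicate_ids]
    return (
        matrix.data.reindex(columns=nt_cols).to_numpy(dtype=float),
        matrix.data.reindex(columns=ref_cols).to_numpy(dtype=float),
    )


def _permutation_pvalues(
    nt: np.ndarray, ref: np.ndarray, t_obs: np.ndarray, n_rounds: int, seed: int
) -> np.ndarray:
    """Label permutation over (channel, replicate) columns, per row.

    p = (1 + #{perm: |t_perm| >= |t_obs|}) / (n_rounds + 1).  Missing values
    stay attached to their cells; rows untestable after permutation count as
    non-exceeding.
    """
    rng = np.random.default_rng(seed)
    values = np.concatenate([nt, ref], axis=1)
    n_a = nt.shape[1]
    exceed = np.zeros(values.shape[0], dtype=int)
    abs_obs = np.abs(t_obs)
    for _ in range(n_rounds):
        perm = rng.permutation(values.shape[1])
        pa, pb = values[:, perm[:n_a]], values[:, perm[n_a:]]
        t_perm = _vector_welch_t(pa, pb)
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(t_perm), False, np.abs(t_perm) >= abs_obs)
    return (1.0 + exceed) / (n_rounds + 1.0)


def _vector_welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        va = np.nanvar(a, axis=1, ddof=1) / na
        vb = np.nanvar(b, axis=1, ddof=1) / nb
        t = (np.nanmean(a, axis=1) - np.nanmean(b, axis=1)) / np.sqrt(va + vb)
    t[(na < 2) | (nb < 2)] = np.nan
    return t


def run_differential(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    permutation: bool = False,
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-row fold change, Welch test and direction classification.

    Returns columns: entity, fc, log2fc, t, df, p, bh_q, direction,
    significant, n_non_type, n_reference, ni.  Selection ("significant")
    uses the raw p-value; bh_q is reported alongside.
    """
    fc_df = fold_changes(matrix, design)
    nt, ref = _group_arrays(matrix, design)

    t_vals = np.full(len(fc_df), np.nan)
    df_vals = np.full(len(fc_df), np.nan)
    p_vals = np.full(len(fc_df), np.nan)
    for i in range(len(fc_df)):
        a = nt[i][~np.isnan(nt[i])]
        b = ref[i][~np.isnan(ref[i])]
        res = welch_ttest(a, b)
        t_vals[i], df_vals[i] = res.t, res.df
        p_vals[i] = np.nan if res.p is None else res.p

    if permutation:
        p_vals = np.where(
            np.isnan(p_vals),
            np.nan,
            _permutation_pvalues(nt, ref, t_vals, n_permutations, seed),
        )

    bh = np.full(len(fc_df), np.nan)
    testable = ~np.isnan(p_vals)
    if testable.any():
        bh[testable] = multipletests(p_vals[testable], method="fdr_bh")[1]

    out = fc_df.copy()
    out["t"] = t_vals
    out["df"] = df_vals
    out["p"] = p_vals
    out["bh_q"] = bh
    out["direction"] = [
        classify_direction(fc, fc_threshold) if np.isfinite(fc) else "unchanged"
        for fc in out["fc"]
    ]
    out["significant"] = testable & (p_vals <= alpha)
    return out


@dataclasses.dataclass
class SignatureSummary:
    n_significant_peptides: int
    n_proteins: int
    n_increased_1p5: int
    n_decreased_1p5: int


def summarize_signature(
    results: pd.DataFrame, entity_to_proteins: dict[str, set[str]] | None = None
) -> SignatureSummary:
    """Counts over the significant set (the differential-glycosylation signature).

    Increased/decreased additionally require the 1.5-fold criterion; the
    remainder of the signature is significant-but-below-1.5-fold.
    """
    sig = results[results["significant"].astype(bool)]
    proteins: set[str] = set()
    if entity_to_proteins:
        for entity in sig["entity"]:
            proteins |= entity_to_proteins.get(entity, set())
    return SignatureSummary(
        n_significant_peptides=int(len(sig)),
        n_proteins=len(proteins),
        n_increased_1p5=int((sig["direction"] == "increased").sum()),
        n_decreased_1p5=int((sig["direction"] == "decreased").sum()),
    )
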