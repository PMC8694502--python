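"""Gene-level translation-efficiency analysis, fold-change filtering and
relative qPCR quantification.

Translation efficiency is the ribosome-footprint abundance of a gene
relative to its mRNA abundance, TE = (RPF CPM + c) / (RNA CPM + c),
replicate-averaged on the log scale.  CPM normalisation makes TE invariant
to library size; CDS length cancels in the KO/control ratio, so no length
normalisation is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .trna import ValidationError

__all__ = [
    "DdctRecord",
    "compute_te",
    "delta_te",
    "fold_change_filter",
    "ddct",
    "ddct_from_table",
    "polysome_te",
]

logger = logging.getLogger(__name__)


def _cpm(counts: pd.DataFrame, lengths: pd.Series | None = None) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("a library has zero total counts")
    cpm = counts / totals * 1e6
    if lengths is not None:
        cpm = cpm.div(lengths / 1e3, axis=0)  # per-kb density, optional
    return cpm


def compute_te(
    rpf_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    pseudocount: float = 0.5,
    cds_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene TE for one condition from matched RPF and RNA replicates.

    Returns a DataFrame with per-replicate ``log2_te`` columns plus ``te``,
    the geometric mean across replicates.  ``cds_lengths`` (nt) switches to
    length-normalised densities; it cancels in any KO/control contrast.
    """
    if not rpf_counts.index.equals(rna_counts.index):
        raise ValidationError("RPF and RNA tables must share the gene index")
    if rpf_counts.shape[1] != rna_counts.shape[1]:
        raise ValidationError("RPF and RNA tables must have matched replicates")
    rpf = _cpm(rpf_counts, cds_lengths)
    rna = _cpm(rna_counts, cds_lengths)
    log2_te = np.log2(
        (rpf.to_numpy() + pseudocount) / (rna.to_numpy() + pseudocount)
    )
    out = pd.DataFrame(
        log2_te,
        index=rpf_counts.index,
        columns=[f"log2_te_{c}" for c in rpf_counts.columns],
    )
    out["te"] = 2.0 ** out.mean(axis=1)
    return out


def delta_te(
    te_ko: pd.DataFrame,
    te_ctrl: pd.DataFrame,
    log2_threshold: float = 0.5,
    fdr: float = 0.05,
    var_mode: str = "pooled",
) -> pd.DataFrame:
    """Classify genes into TE_down / TE_up / unchanged, KO vs control.

    The replicate test contrasts log2 TE between conditions.  The default
    ``pooled`` mode uses a common variance pooled across genes (replicate
    log-TE noise is approximately homoscedastic and per-gene df with n=3 is
    too small to reach corrected significance); ``welch`` runs a per-gene
    Welch t-test.  With a single replicate on either side the test is
    skipped and classification is threshold-only (logged).
    """
    rep_ko = te_ko.filter(like="log2_te_")
    rep_ctrl = te_ctrl.filter(like="log2_te_")
    if not te_ko.index.equals(te_ctrl.index):
        raise ValidationError("TE tables must share the gene index")
    d = rep_ko.mean(axis=1) - rep_ctrl.mean(axis=1)
    n1, n2 = rep_ko.shape[1], rep_ctrl.shape[1]
    if n1 >= 2 and n2 >= 2:
        if var_mode == "pooled":
            s2 = (
                rep_ko.var(axis=1, ddof=1) * (n1 - 1)
                + rep_ctrl.var(axis=1, ddof=1) * (n2 - 1)
            ) / (n1 + n2 - 2)
            se = np.sqrt(s2.mean() * (1 / n1 + 1 / n2))
            z = d / se
            p = 2 * stats.norm.sf(np.abs(z))
        elif var_mode == "welch":
            _, p = stats.ttest_ind(rep_ko, rep_ctrl, axis=1, equal_var=False)
            p = np.where(np.isfinite(p), p, 1.0)
        else:
            raise ValidationError(f"unknown var_mode {var_mode!r}")
        q = stats.false_discovery_control(p)
        tested = True
    else:
        logger.warning("single replicate: TE test skipped, threshold-only classes")
        p = np.full(len(d), np.nan)
        q = np.full(len(d), np.nan)
        tested = False
    sig = (q <= fdr) if tested else np.ones(len(d), dtype=bool)
    te_class = np.where(
        (d <= -log2_threshold) & sig,
        "TE_down",
        np.where((d >= log2_threshold) & sig, "TE_up", "unchanged"),
    )
    return pd.DataFrame(
        {
            "te_ko": te_ko["te"],
            "te_ctrl": te_ctrl["te"],
            "log2_dte": d,
            "pvalue": p,
            "qvalue": q,
            "te_class": te_class,
        },
        index=te_ko.index,
    )


def fold_change_filter(
    ratios: "pd.Series | Mapping[str, float]", fc_threshold: float = 2.0
) -> tuple[list[str], list[str]]:
    """Split genes into up/down lists by expression ratio.

    ``up`` iff ratio >= fc_threshold; ``down`` iff ratio <= 1/fc_threshold.
    """
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must exceed 1")
    s = pd.Series(ratios, dtype=float)
    if (s <= 0).any() or not np.isfinite(s).all():
        bad = s.index[(s <= 0) | ~np.isfinite(s)].tolist()
        raise ValidationError(f"nonpositive or non-finite ratios for {bad}")
    up = sorted(s.index[s >= fc_threshold])
    down = sorted(s.index[s <= 1 / fc_threshold])
    return up, down


@dataclass(frozen=True)
class DdctRecord:
    """Relative qPCR quantification by the 2^(-ddCt) method."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float
    ddct: float
    relative_expression: float


def ddct(
    ct_target_treated: "float | Iterable[float]",
    ct_ref_treated: "float | Iterable[float]",
    ct_target_control: "float | Iterable[float]",
    ct_ref_control: "float | Iterable[float]",
) -> DdctRecord:
    """delta-delta-Ct: replicate inputs are averaged first.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control;
    relative expression = 2^(-ddCt).  Exact closed-form arithmetic.
    """
    vals = [
        float(np.mean(np.asarray(v, dtype=float)))
        for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    ]
    if not all(np.isfinite(vals)):
        raise ValidationError("Ct values must be finite")
    tt, rt, tc, rc = vals
    d = (tt - rt) - (tc - rc)
    return DdctRecord(
        ct_target_treated=tt,
        ct_ref_treated=rt,
        ct_target_control=tc,
        ct_ref_control=rc,
        ddct=d,
        relative_expression=2.0 ** (-d),
    )


def ddct_from_table(
    table: pd.DataFrame,
    target: str = "target",
    reference: str = "reference",
    treated: str = "treated",
    control: str = "control",
) -> DdctRecord:
    """ddct on a tidy Ct table with columns (gene, condition, replicate, ct)."""
    def _ct(gene: str, condition: str) -> np.ndarray:
        sel = table[(table["gene"] == gene) & (table["condition"] == condition)]
        if sel.empty:
            raise ValidationError(f"no Ct rows for ({gene}, {condition})")
        return sel["ct"].to_numpy()

    return ddct(
        _ct(target, treated), _ct(reference, treated),
        _ct(target, control), _ct(reference, control),
    )


def polysome_te(
    input_levels: pd.DataFrame, polysome_levels: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene polysome-association ratio per condition.

    Inputs are gene x condition tables of relative expression levels (from
    ``ddct`` per gene, or CPM).  The ratio is polysome-bound / input; when
    both ``KO`` and ``CTRL`` columns are present a ``ko_vs_ctrl`` contrast
    is added.  Genes missing from either table are excluded and logged.
    """
    common = input_levels.index.intersection(polysome_levels.index)
    dropped = len(input_levels.index.symmetric_difference(polysome_levels.index))
    if dropped:
        logger.info("polysome_te: %d genes present in one table only", dropped)
    if common.empty:
        raise ValidationError("no genes shared between input and polysome tables")
    cols = [c for c in input_levels.columns if c in polysome_levels.columns]
    out = polysome_levels.loc[common, cols] / input_levels.loc[common, cols]
    out.columns = [f"ratio_{c}" for c in cols]
    if "ratio_KO" in out.columns and "ratio_CTRL" in out.columns:
        out["ko_vs_ctrl"] = out["ratio_KO"] / out["ratio_CTRL"]
    return out
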