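"""Ribo-seq analysis: A-site assignment, metagene distribution, per-codon
pause scores and KO-vs-control occupancy contrasts by codon class.

The A-site nucleotide of a footprint is ``start + offset[length]``; the
pause score of one codon occurrence is its footprint count divided by the
mean count over the transcript's CDS codons, so scores average 1 per
transcript and are invariant to library depth.  The A+1 table attributes
each count to the codon one position 3'-ward, the standard within-gene
control: a genuine decoding pause follows the A-site codon identity and
disappears at A+1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trna import CODON_TO_AA, CodonClass, CodonClassMap, CodonDecodingTable, ValidationError, wc_codon

if TYPE_CHECKING:  # transcripts are duck-typed: id, sequence, cds_start, cds_end
    from .simulate import Transcript

__all__ = [
    "DEFAULT_OFFSETS",
    "CodonCounts",
    "AssignmentStats",
    "MetageneProfile",
    "CorrelationReport",
    "assign_a_site",
    "metagene_distribution",
    "codon_occupancy",
    "occupancy_change",
    "correlate_abundance_occupancy",
]

logger = logging.getLogger(__name__)

#: footprint length -> nt from the 5' end to the first base of the A-site codon
DEFAULT_OFFSETS: Mapping[int, int] = {26: 14, 27: 14, 28: 15, 29: 15, 30: 16, 31: 16}


@dataclass
class CodonCounts:
    """A-site footprint counts over one transcript's CDS codons."""

    codons: list[str]
    counts: np.ndarray


@dataclass
class AssignmentStats:
    n_input: int = 0
    n_cds: int = 0
    n_utr: int = 0
    n_discarded_length: int = 0
    n_unknown_transcript: int = 0

    @property
    def conserved(self) -> bool:
        return (
            self.n_cds + self.n_utr + self.n_discarded_length + self.n_unknown_transcript
            == self.n_input
        )


@dataclass(frozen=True)
class MetageneProfile:
    """Fractions of footprints whose A-site falls in each transcript region."""

    utr5: float
    cds: float
    utr3: float


def _a_sites(
    footprints: pd.DataFrame, offsets: Mapping[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(A-site nt per footprint, mask of footprints with a listed length)."""
    lengths = footprints["length"].to_numpy()
    known = np.isin(lengths, list(offsets))
    off = footprints["length"].map(offsets).to_numpy(dtype=float)
    a_nt = footprints["start"].to_numpy() + np.where(known, off, 0).astype(int)
    return a_nt, known


def assign_a_site(
    footprints: pd.DataFrame,
    transcripts: Sequence["Transcript"],
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> tuple[dict[str, CodonCounts], AssignmentStats]:
    """Map footprints to A-site codon counts per transcript.

    Footprints with unlisted lengths are discarded (and counted); ones on
    transcripts absent from the annotation are skipped (and counted); ones
    whose A-site lies outside the CDS are counted as UTR.  The codon index
    is ``(a_nt - cds_start) // 3`` (integer division absorbs frame).
    """
    by_id = {t.id: t for t in transcripts}
    stats_ = AssignmentStats(n_input=len(footprints))
    counts = {
        t.id: CodonCounts(codons=t.codons(), counts=np.zeros(t.n_codons))
        for t in transcripts
    }
    a_nt, known = _a_sites(footprints, offsets)
    stats_.n_discarded_length = int((~known).sum())
    df = pd.DataFrame(
        {"transcript": footprints["transcript"].to_numpy()[known], "a": a_nt[known]}
    )
    for tid, grp in df.groupby("transcript", sort=False):
        t = by_id.get(tid)
        if t is None:
            stats_.n_unknown_transcript += len(grp)
            continue
        a = grp["a"].to_numpy()
        in_cds = (a >= t.cds_start) & (a < t.cds_end)
        stats_.n_utr += int((~in_cds).sum())
        stats_.n_cds += int(in_cds.sum())
        idx = (a[in_cds] - t.cds_start) // 3
        np.add.at(counts[tid].counts, idx, 1)
    if stats_.n_discarded_length or stats_.n_unknown_transcript:
        logger.info(
            "assign_a_site: %d discarded (length), %d unknown transcript",
            stats_.n_discarded_length,
            stats_.n_unknown_transcript,
        )
    return counts, stats_


def metagene_distribution(
    footprints: pd.DataFrame,
    transcripts: Sequence["Transcript"],
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> MetageneProfile:
    """Fractions of footprints in 5'UTR / CDS / 3'UTR, by A-site position."""
    if footprints.empty:
        raise ValidationError("no footprints")
    by_id = {t.id: t for t in transcripts}
    a_nt, known = _a_sites(footprints, offsets)
    tids = footprints["transcript"].to_numpy()[known]
    a_nt = a_nt[known]
    n5 = ncds = n3 = 0
    df = pd.DataFrame({"transcript": tids, "a": a_nt})
    for tid, grp in df.groupby("transcript", sort=False):
        t = by_id.get(tid)
        if t is None:
            continue
        a = grp["a"].to_numpy()
        n5 += int((a < t.cds_start).sum())
        ncds += int(((a >= t.cds_start) & (a < t.cds_end)).sum())
        n3 += int((a >= t.cds_end).sum())
    total = n5 + ncds + n3
    if total == 0:
        raise ValidationError("no footprints on annotated transcripts")
    return MetageneProfile(utr5=n5 / total, cds=ncds / total, utr3=n3 / total)


def codon_occupancy(
    codon_counts: Mapping[str, CodonCounts],
    class_map: CodonClassMap,
    min_transcript_rpf: float = 64,
    min_occurrences: int = 100,
) -> pd.DataFrame:
    """Per-codon pause statistics at the A and A+1 sites for one condition.

    Transcripts with fewer than ``min_transcript_rpf`` assigned footprints
    are excluded.  The per-codon statistic is the mean over occurrences
    (median reported alongside); codons with fewer than ``min_occurrences``
    occurrences at a site get NaN there.  Stop codons are excluded from the
    codon universe but remain in each transcript's normalising mean.
    """
    if min_transcript_rpf < 0 or min_occurrences < 0:
        raise ValidationError("thresholds must be nonnegative")
    codons_a, scores_a, codons_a1, scores_a1 = [], [], [], []
    n_used = 0
    for tid, cc in codon_counts.items():
        total = cc.counts.sum()
        if total < min_transcript_rpf or len(cc.codons) == 0:
            continue
        n_used += 1
        scores = cc.counts / cc.counts.mean()
        codon_arr = np.array(cc.codons)
        codons_a.append(codon_arr)
        scores_a.append(scores)
        # A+1: the count at codon j-1 is attributed to codon j
        codons_a1.append(codon_arr[1:])
        scores_a1.append(scores[:-1])
    if n_used == 0:
        raise ValidationError("no transcript passes min_transcript_rpf")

    def _site_table(codons: list, scores: list, suffix: str) -> pd.DataFrame:
        s = pd.Series(
            np.concatenate(scores), index=np.concatenate(codons), name="score"
        )
        s = s[s.index.isin(CODON_TO_AA)]
        g = s.groupby(level=0)
        tab = pd.DataFrame(
            {
                f"mean_{suffix}": g.mean(),
                f"median_{suffix}": g.median(),
                f"n_{suffix}": g.size(),
            }
        )
        low = tab[f"n_{suffix}"] < min_occurrences
        tab.loc[low, [f"mean_{suffix}", f"median_{suffix}"]] = np.nan
        return tab

    out = _site_table(codons_a, scores_a, "a").join(
        _site_table(codons_a1, scores_a1, "a1"), how="outer"
    )
    out.index.name = "codon"
    out["codon_class"] = [str(class_map[c]) for c in out.index]
    return out


def occupancy_change(
    ko: pd.DataFrame, ctrl: pd.DataFrame, test: str = "welch"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-codon KO/control pause ratios and the class-level contrast.

    Returns ``(codon_table, class_tests)``.  The codon table carries
    ``ratio_a`` and ``ratio_a1``; codons present (with finite statistics) in
    only one condition are excluded and logged.  The class test compares
    M7G_DECODED vs NON_M7G ratio distributions at each site, BH-corrected
    across the two sites.  The default is Welch's t on log2 ratios: the two
    classes have unequal codon-occurrence counts and therefore unequal
    ratio variances, which a rank-sum test conflates with a location shift
    (inflating its type-I error under the null); ``test="ranksum"`` selects
    the two-sided Wilcoxon rank-sum instead.
    """
    common = ko.index.intersection(ctrl.index)
    dropped = len(ko.index.symmetric_difference(ctrl.index))
    if dropped:
        logger.info("occupancy_change: %d codons present in one table only", dropped)
    merged = ko.loc[common].join(ctrl.loc[common], lsuffix="_ko", rsuffix="_ctrl")
    if (merged["codon_class_ko"] != merged["codon_class_ctrl"]).any():
        raise ValidationError("codon class labels differ between conditions")
    out = pd.DataFrame(index=common)
    out.index.name = "codon"
    out["codon_class"] = merged["codon_class_ko"]
    for site in ("a", "a1"):
        out[f"ratio_{site}"] = merged[f"mean_{site}_ko"] / merged[f"mean_{site}_ctrl"]
        out[f"n_{site}_ko"] = merged[f"n_{site}_ko"]
        out[f"n_{site}_ctrl"] = merged[f"n_{site}_ctrl"]

    if test not in ("welch", "ranksum"):
        raise ValidationError(f"unknown class test {test!r}")
    rows = []
    for site in ("a", "a1"):
        r = out[f"ratio_{site}"]
        m7g = r[(out["codon_class"] == str(CodonClass.M7G_DECODED)) & r.notna()]
        non = r[(out["codon_class"] == str(CodonClass.NON_M7G)) & r.notna()]
        if len(m7g) > 1 and len(non) > 1 and (m7g.nunique() > 1 or non.nunique() > 1):
            if test == "welch":
                p = float(
                    stats.ttest_ind(np.log2(m7g), np.log2(non), equal_var=False).pvalue
                )
            else:
                p = float(stats.ranksums(m7g, non).pvalue)
        else:
            p = 1.0
        rows.append(
            {
                "site": site.upper().replace("A1", "A+1"),
                "n_m7g": len(m7g),
                "n_non_m7g": len(non),
                "median_m7g": float(m7g.median()) if len(m7g) else np.nan,
                "median_non_m7g": float(non.median()) if len(non) else np.nan,
                "pvalue": p,
            }
        )
    tests = pd.DataFrame(rows)
    tests["qvalue"] = stats.false_discovery_control(tests["pvalue"].to_numpy())
    return out, tests


@dataclass
class CorrelationReport:
    """Spearman association between m7G-tRNA abundance change and the A-site
    occupancy ratio of each species' WC codon."""

    pairs: pd.DataFrame  # codon, species log2fc (cognate mean), log2 A-site ratio
    rho: float
    pvalue: float
    degenerate: bool
    permuted_abs_rho: np.ndarray | None = None


def correlate_abundance_occupancy(
    trna_table: pd.DataFrame,
    codon_ratios: pd.DataFrame,
    decoding_table: CodonDecodingTable,
    m7g_ids: frozenset[str] | set[str],
    n_permutations: int = 0,
    seed: int = 0,
) -> CorrelationReport:
    """Pair each M7G_DECODED codon's log2 A-site ratio with the mean log2
    abundance fold change of its m7G WC cognates; Spearman correlation.

    ``trna_table`` is the output of ``quantify_trna_abundance`` (needs a
    ``log2fc`` column); ``codon_ratios`` the codon table from
    ``occupancy_change``.  Degenerate inputs (constant x or y) are flagged
    rather than tested.  Optional label permutations give the null |rho|.
    """
    rows = []
    for codon, row in codon_ratios.iterrows():
        if row["codon_class"] != str(CodonClass.M7G_DECODED):
            continue
        if not np.isfinite(row["ratio_a"]) or row["ratio_a"] <= 0:
            continue
        cognates = sorted(decoding_table.wc_cognates[codon] & set(m7g_ids))
        cognates = [s for s in cognates if s in trna_table.index]
        if not cognates:
            continue
        rows.append(
            {
                "codon": codon,
                "species": ",".join(cognates),
                "species_log2fc": float(trna_table.loc[cognates, "log2fc"].mean()),
                "log2_ratio_a": float(np.log2(row["ratio_a"])),
            }
        )
    if not rows:
        raise ValidationError("no (species, codon) pairs to correlate")
    pairs = pd.DataFrame(rows)
    x = pairs["species_log2fc"].to_numpy()
    y = pairs["log2_ratio_a"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0 or len(pairs) < 3:
        return CorrelationReport(pairs=pairs, rho=np.nan, pvalue=np.nan, degenerate=True)
    res = stats.spearmanr(x, y)
    perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm = np.array(
            [
                abs(stats.spearmanr(rng.permutation(x), y).statistic)
                for _ in range(n_permutations)
            ]
        )
    return CorrelationReport(
        pairs=pairs,
        rho=float(res.statistic),
        pvalue=float(res.pvalue),
        degenerate=False,
        permuted_abs_rho=perm,
    )
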