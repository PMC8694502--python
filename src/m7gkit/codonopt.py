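"""Codon-usage scoring and synonymous recoding of CDSs.

Transcripts enriched in m7G-tRNA-decoded codons are the ones whose
translation is most sensitive to loss of the modification; the gene-level
score is the fraction of sense codons in the M7G_DECODED class.  The mutant
designer replaces target codons with synonymous NON_M7G codons, preserving
the protein, which is how codon dependence is tested experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .trna import (
    AA_TO_CODONS,
    CODON_TO_AA,
    STOP_CODONS,
    CodonClass,
    CodonClassMap,
    CodonDecodingTable,
    ValidationError,
)

__all__ = [
    "CDSRecord",
    "CodonUsageProfile",
    "MutantDesign",
    "UnsatisfiableDesignError",
    "codon_usage_profile",
    "design_synonymous_mutant",
    "rank_genes_by_m7g_usage",
]


class UnsatisfiableDesignError(ValueError):
    """A target codon's amino acid has no NON_M7G synonymous codon."""

    def __init__(self, amino_acid: str, codon: str):
        self.amino_acid = amino_acid
        self.codon = codon
        super().__init__(
            f"no NON_M7G synonymous codon for {amino_acid} (target codon {codon})"
        )


@dataclass(frozen=True)
class CDSRecord:
    """A coding sequence, 5'->3', length divisible by 3, no internal stop."""

    id: str
    sequence: str
    require_start: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise ValidationError(f"{self.id}: CDS length not divisible by 3")
        codons = self.codons()
        body = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
        for i, c in enumerate(body):
            if c in STOP_CODONS:
                raise ValidationError(f"{self.id}: internal stop codon at index {i}")
            if c not in CODON_TO_AA:
                raise ValidationError(f"{self.id}: invalid codon {c!r} at index {i}")
        if self.require_start and (not codons or codons[0] != "ATG"):
            raise ValidationError(f"{self.id}: CDS does not start with ATG")

    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]

    def translate(self) -> str:
        return str(Seq(self.sequence).translate())


@dataclass(frozen=True)
class CodonUsageProfile:
    """Per-amino-acid codon counts by decoding class, and the gene-level
    m7G-codon fraction (m7G-decoded codons / total sense codons)."""

    counts: pd.DataFrame  # index: amino acid, columns: the three classes
    n_sense: int
    m7g_fraction: float


def codon_usage_profile(cds: CDSRecord, classes: CodonClassMap) -> CodonUsageProfile:
    """Exhaustively tally a CDS's sense codons by decoding class."""
    cols = [str(c) for c in CodonClass]
    tallies: dict[str, dict[str, int]] = {}
    n_sense = 0
    n_m7g = 0
    for codon in cds.codons():
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA[codon]
        cls = str(classes[codon])
        tallies.setdefault(aa, {c: 0 for c in cols})[cls] += 1
        n_sense += 1
        if cls == str(CodonClass.M7G_DECODED):
            n_m7g += 1
    counts = pd.DataFrame.from_dict(tallies, orient="index").reindex(columns=cols)
    counts = counts.fillna(0).astype(int).sort_index()
    counts.index.name = "amino_acid"
    return CodonUsageProfile(
        counts=counts,
        n_sense=n_sense,
        m7g_fraction=n_m7g / n_sense if n_sense else 0.0,
    )


@dataclass(frozen=True)
class MutantDesign:
    """Edits (codon index, original, replacement) and the recoded CDS."""

    edits: tuple[tuple[int, str, str], ...]
    sequence: str


def design_synonymous_mutant(
    cds: CDSRecord,
    classes: CodonClassMap,
    table: CodonDecodingTable | None = None,
    target: "Iterable[str] | str" = "ALL_M7G",
) -> MutantDesign:
    """Replace every occurrence of a target codon with a NON_M7G synonym.

    ``target`` is a set of sense codons or ``"ALL_M7G"`` (every M7G_DECODED
    codon).  The replacement is the lexicographically smallest synonymous
    NON_M7G codon -- a deterministic tie-break; when a decoding table is
    supplied, synonyms with at least one cognate tRNA gene are preferred
    (falling back to all NON_M7G synonyms).  Targeting a codon whose amino
    acid has no NON_M7G synonym (single-codon Met/Trp when modified) raises
    :class:`UnsatisfiableDesignError`.
    """
    if isinstance(target, str):
        if target != "ALL_M7G":
            raise ValidationError(f"unknown target selector {target!r}")
        targets = set(classes.codons_in(CodonClass.M7G_DECODED))
    else:
        targets = set(target)
        bad = targets - set(CODON_TO_AA)
        if bad:
            raise ValidationError(f"targets are not sense codons: {sorted(bad)}")

    replacement: dict[str, str] = {}
    for codon in sorted(targets):
        aa = CODON_TO_AA[codon]
        synonyms = [
            c
            for c in AA_TO_CODONS[aa]
            if c != codon and classes[c] is CodonClass.NON_M7G
        ]
        if classes[codon] is CodonClass.NON_M7G:
            synonyms.append(codon)  # already acceptable: identity allowed
        if table is not None:
            with_cognate = [c for c in synonyms if table.cognates(c)]
            if with_cognate:
                synonyms = with_cognate
        if not synonyms:
            raise UnsatisfiableDesignError(aa, codon)
        replacement[codon] = min(synonyms)

    edits = []
    out = []
    for i, codon in enumerate(cds.codons()):
        new = replacement.get(codon, codon)
        if new != codon:
            edits.append((i, codon, new))
        out.append(new)
    mutant = "".join(out)
    design = MutantDesign(edits=tuple(edits), sequence=mutant)
    assert CDSRecord(id=f"{cds.id}|mut", sequence=mutant).translate() == cds.translate()
    return design


def rank_genes_by_m7g_usage(
    cds_list: Sequence[CDSRecord], classes: CodonClassMap
) -> pd.DataFrame:
    """Rank genes by m7G-codon fraction, descending; ties broken by id."""
    if not cds_list:
        raise ValidationError("no CDS records")
    rows = [
        {
            "gene": cds.id,
            "n_sense_codons": (p := codon_usage_profile(cds, classes)).n_sense,
            "m7g_fraction": p.m7g_fraction,
        }
        for cds in cds_list
    ]
    out = pd.DataFrame(rows).sort_values(
        ["m7g_fraction", "gene"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)
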