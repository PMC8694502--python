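"""tRNA species model and the codon -> tRNA decoding map with wobble rules.

The central object is a three-way partition of the 61 sense codons:

* ``M7G_DECODED`` -- codons whose Watson-Crick cognate tRNA carries the
  variable-loop m7G modification (position 46 in Sprinzl numbering);
* ``WOBBLE_ONLY`` -- codons with no Watson-Crick cognate tRNA gene in the
  supplied reference set, i.e. readable only through wobble pairing at
  anticodon position 34;
* ``NON_M7G`` -- codons whose Watson-Crick cognate tRNAs are all unmodified.

Ribosome-occupancy and codon-usage analyses downstream compare these classes.
The m7G species set is always an input (an annotation or a TRAC-seq call set),
never hard-coded: the modified subset is cell-type specific.

DNA alphabet (T, not U) is used throughout; report layers may render U.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_TO_AA",
    "CodonClass",
    "TRNASpecies",
    "WobbleRuleSet",
    "CodonDecodingTable",
    "CodonClassMap",
    "AlphabetError",
    "ValidationError",
    "revcomp",
    "wc_codon",
    "build_decoding_table",
    "classify_codons",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")

_TABLE1 = unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE1.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if "".join(c) not in STOP_CODONS
    )
)
#: codon -> three-letter amino acid code (standard genetic code, table 1)
CODON_TO_AA: Mapping[str, str] = {
    c: seq3(_TABLE1.forward_table[c]) for c in SENSE_CODONS
}
#: three-letter amino acid code -> tuple of synonymous sense codons
AA_TO_CODONS: Mapping[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa))
    for aa in sorted(set(CODON_TO_AA.values()))
}


class AlphabetError(ValueError):
    """A sequence contains characters outside the DNA alphabet."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class CodonClass(str, Enum):
    M7G_DECODED = "M7G_DECODED"
    WOBBLE_ONLY = "WOBBLE_ONLY"
    NON_M7G = "NON_M7G"

    def __str__(self) -> str:  # so f-strings and TSV export print the label
        return self.value


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    if not _DNA.issuperset(seq):
        raise AlphabetError(f"non-ACGT character in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def wc_codon(anticodon: str) -> str:
    """Codon read by strict Watson-Crick pairing of a 5'->3' anticodon.

    Codon position 3 pairs anticodon position 34 (the anticodon's 5' base),
    so the codon is simply the reverse complement.  Involutive: applying the
    map to the reverse complement of a codon returns the codon.
    """
    if len(anticodon) != 3:
        raise ValidationError(f"anticodon must be 3 bases, got {anticodon!r}")
    return revcomp(anticodon)


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA gene/isodecoder with its candidate m7G variable-loop site.

    ``variable_loop_site`` is the 0-based index of the candidate m7G
    guanosine (the Sprinzl-46 analogue).  ``is_m7g`` marks the species as
    modified -- either planted truth (simulation) or a TRAC-seq call.
    """

    id: str
    amino_acid: str
    anticodon: str
    sequence: str
    variable_loop_site: int
    is_m7g: bool = False

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or not _DNA.issuperset(self.anticodon):
            raise ValidationError(
                f"{self.id}: anticodon must be 3 DNA bases, got {self.anticodon!r}"
            )
        if not _DNA.issuperset(self.sequence):
            raise AlphabetError(f"{self.id}: non-ACGT character in sequence")
        if not 0 <= self.variable_loop_site < len(self.sequence):
            raise ValidationError(
                f"{self.id}: variable_loop_site {self.variable_loop_site} outside "
                f"sequence of length {len(self.sequence)}"
            )
        if self.is_m7g and self.sequence[self.variable_loop_site] != "G":
            raise ValidationError(
                f"{self.id}: flagged m7G but base at {self.variable_loop_site} is "
                f"{self.sequence[self.variable_loop_site]!r}, not G"
            )


@dataclass(frozen=True)
class WobbleRuleSet:
    """Decoding capability of anticodon position 34 (the 5' anticodon base).

    ``pairing`` maps each possible base at position 34 to the set of codon
    third-position bases it can read.  Every set must contain the
    Watson-Crick partner.  ``inosine_mode`` treats A34 as inosine, which
    reads {T, C, A}; with it off A34 reads only its WC partner T.
    """

    pairing: Mapping[str, frozenset[str]]
    inosine_mode: bool = True

    def __post_init__(self) -> None:
        for base in "ACGT":
            allowed = self.pairing.get(base)
            if not allowed:
                raise ValidationError(f"pairing set for anticodon base {base} is empty")
            if not _DNA.issuperset(allowed):
                raise AlphabetError(f"pairing set for {base} has non-ACGT members")
            wc = base.translate(_COMPLEMENT)
            if wc not in allowed:
                raise ValidationError(
                    f"pairing set for anticodon base {base} lacks its WC partner {wc}"
                )

    @classmethod
    def default(cls, inosine_mode: bool = True) -> "WobbleRuleSet":
        """Crick wobble rules: G34 reads C/T, T34 reads A/G, C34 reads G,
        A34 reads T (or T/C/A when treated as inosine)."""
        pairing = {
            "G": frozenset("CT"),
            "T": frozenset("AG"),
            "C": frozenset("G"),
            "A": frozenset("TCA") if inosine_mode else frozenset("T"),
        }
        return cls(pairing=pairing, inosine_mode=inosine_mode)


@dataclass(frozen=True)
class CodonDecodingTable:
    """For every sense codon, which species read it by WC pairing and which
    only through a wobble rule.  The two sets are disjoint by construction."""

    wc_cognates: Mapping[str, frozenset[str]]
    wobble_cognates: Mapping[str, frozenset[str]]
    species_ids: frozenset[str]

    def cognates(self, codon: str) -> frozenset[str]:
        return self.wc_cognates[codon] | self.wobble_cognates[codon]


@dataclass(frozen=True)
class CodonClassMap:
    """The three-way partition of the 61 sense codons."""

    class_of: Mapping[str, CodonClass]

    def __post_init__(self) -> None:
        if set(self.class_of) != set(SENSE_CODONS):
            raise ValidationError("class map must cover exactly the 61 sense codons")

    def codons_in(self, cls: CodonClass) -> tuple[str, ...]:
        return tuple(c for c in SENSE_CODONS if self.class_of[c] is cls)

    def __getitem__(self, codon: str) -> CodonClass:
        return self.class_of[codon]


def build_decoding_table(
    species: Iterable[TRNASpecies], rules: WobbleRuleSet | None = None
) -> CodonDecodingTable:
    """Map every sense codon to its WC and wobble-only cognate species.

    A species is a wobble cognate of codon ``c`` iff ``wc_codon(anticodon)``
    and ``c`` agree at positions 1-2, differ at position 3, and the wobble
    rule for the anticodon's position-34 base admits ``c``'s third base.
    """
    rules = rules or WobbleRuleSet.default()
    species = list(species)
    if not species:
        raise ValidationError("species list is empty")
    ids = [sp.id for sp in species]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate species ids: {dup}")

    wc: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    wobble: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    for sp in species:
        cognate = wc_codon(sp.anticodon)
        if cognate in wc:
            wc[cognate].add(sp.id)
        allowed_third = rules.pairing[sp.anticodon[0]]
        for third in allowed_third:
            codon = cognate[:2] + third
            if codon != cognate and codon in wobble:
                wobble[codon].add(sp.id)
    return CodonDecodingTable(
        wc_cognates={c: frozenset(v) for c, v in wc.items()},
        wobble_cognates={c: frozenset(v) for c, v in wobble.items()},
        species_ids=frozenset(ids),
    )


def classify_codons(
    table: CodonDecodingTable, m7g_ids: Iterable[str]
) -> CodonClassMap:
    """Partition the sense codons given the set of m7G-modified species.

    A codon with no WC cognate gene in the reference set is ``WOBBLE_ONLY``
    (decodable, if at all, only via wobble); otherwise it is ``M7G_DECODED``
    when any WC cognate is modified, else ``NON_M7G``.
    """
    m7g = frozenset(m7g_ids)
    unknown = m7g - table.species_ids
    if unknown:
        raise ValidationError(f"unknown species ids in m7g set: {sorted(unknown)}")
    class_of: dict[str, CodonClass] = {}
    for codon in SENSE_CODONS:
        cognates = table.wc_cognates[codon]
        if not cognates:
            class_of[codon] = CodonClass.WOBBLE_ONLY
        elif cognates & m7g:
            class_of[codon] = CodonClass.M7G_DECODED
        else:
            class_of[codon] = CodonClass.NON_M7G
    return CodonClassMap(class_of=class_of)
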