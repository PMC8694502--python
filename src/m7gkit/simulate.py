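"""Seeded generators for every input the pipeline consumes, with truth tables.

The generators emulate the statistical structure of the four assay types the
pipeline analyses:

* TRAC-seq -- chemical reduction/scission cleaves the tRNA backbone at m7G,
  so modified positions appear as site-specific read ends in a treated
  library but not in the matched input library.  Cleavage destroys the
  modified base: the 5' fragment ends at ``site - 1`` and the 3' fragment
  starts at ``site + 1``.
* Ribo-seq -- ribosome-protected fragments (26-31 nt) sampled along
  transcripts proportional to codon dwell weights; in the knockout
  condition, codons decoded by m7G tRNAs carry a dwell multiplier.
* RNA-seq / RPF counting -- gene-level negative-binomial counts with planted
  translation-efficiency shifts on a subset of genes.
* RT-qPCR -- Ct values whose noise-free delta-delta-Ct inverts exactly to a
  planted fold change.

Every generator is a pure function of its configuration (including the
seed): reruns are byte-identical.  The truth tables fully determine the
expected value of every downstream estimator, and small counting oracles are
provided for tests (they look only at the raw simulated records, never at
the pipeline's own estimators).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .trna import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    CodonClass,
    CodonClassMap,
    CodonDecodingTable,
    TRNASpecies,
    ValidationError,
    revcomp,
    wc_codon,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Transcript",
    "Condition",
    "DEFAULT_OFFSETS",
    "simulate_trna_reference",
    "simulate_tracseq_reads",
    "simulate_trna_counts",
    "simulate_transcriptome",
    "simulate_ribo_rna",
    "simulate_qpcr",
    "count_site_cleavage",
    "class_instance_fraction",
    "dwell_by_class",
]

Condition = Literal["CTRL", "KO"]

# The A-site offset table is shared with the Ribo-seq analyser so tests are
# convention-independent.
from .riboseq import DEFAULT_OFFSETS  # noqa: E402

_FOOTPRINT_LENGTHS = np.array(sorted(DEFAULT_OFFSETS))
#: length distribution peaked at 28 nt, the canonical human RPF size
_FOOTPRINT_LENGTH_PROBS = np.array([0.08, 0.18, 0.35, 0.20, 0.12, 0.07])

_BASES = np.array(list("ACGT"))


def _rng(seed: int, *tags: object) -> np.random.Generator:
    """Independent, order-insensitive substream per generator stage."""
    entropy = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default desk-scale design.

    Scales (40 tRNA species, 300 genes, 2e5 TRAC-seq reads and 5e5
    footprints per library) are chosen so a full run takes minutes on one
    CPU while every planted effect is comfortably detectable.
    """

    seed: int = 1
    # --- tRNA reference ---
    n_trna_species: int = 40
    n_m7g: int = 15
    trna_len_range: tuple[int, int] = (70, 90)
    variable_loop_site: int = 45  # the Sprinzl-46 analogue, 0-based
    # --- TRAC-seq ---
    tracseq_depth: int = 200_000  # reads per library
    p_cleave: float = 0.7  # treated-library cleavage probability at a planted site
    p_bg: float = 0.01  # background cleavage probability per covered G
    min_fragment_len: int = 15  # shorter fragments are lost in library prep
    # --- transcriptome ---
    n_genes: int = 300
    cds_length_range: tuple[int, int] = (150, 400)  # codons, excl. start/stop
    utr5_len: int = 50
    utr3_len: int = 50
    m7g_codon_share: float = 0.08  # within-family usage share per m7G-decoded codon
    # --- Ribo-seq ---
    ribo_depth: int = 500_000  # footprints per library
    cds_fraction: float = 0.85  # fraction of footprints with A-site in the CDS
    pause_factor: float = 2.0  # KO dwell multiplier at M7G_DECODED codons
    couple_dwell_to_abundance: bool = False
    coupled_log2fc_range: tuple[float, float] = (-2.5, -0.5)
    # --- counts ---
    rna_depth: int = 1_000_000
    nb_dispersion: float = 0.01  # variance = mu + phi * mu^2
    n_replicates: int = 3
    te_effect_genes: float = 0.1  # fraction of genes with a planted TE shift
    te_effect_size: float = -1.0  # planted log2 delta-TE in KO
    # --- tRNA abundance / qPCR ---
    trna_fc: float = -1.0  # planted log2 fold change of m7G-tRNA abundance in KO
    n_down_m7g: int | None = None  # plant trna_fc on this many m7G species (None = all)
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_m7g > self.n_trna_species:
            raise ValidationError("n_m7g cannot exceed n_trna_species")
        for name in ("p_cleave", "p_bg", "cds_fraction", "te_effect_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.pause_factor <= 0:
            raise ValidationError("pause_factor must be positive")
        for name in ("tracseq_depth", "ribo_depth", "rna_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_down_m7g is not None and self.n_down_m7g > self.n_m7g:
            raise ValidationError("n_down_m7g cannot exceed n_m7g")
        if self.variable_loop_site < 3 or self.variable_loop_site + 2 > self.trna_len_range[0]:
            raise ValidationError("variable_loop_site must leave room for the 5-mer context")


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed to one simulated study.

    Filled incrementally as generators run: the tRNA reference plants sites,
    contexts and abundance fold changes; the Ribo-seq/counts generator adds
    per-gene TE shifts and per-codon dwell multipliers.
    """

    planted_sites: list[tuple[str, int]] = field(default_factory=list)
    planted_contexts: dict[str, str] = field(default_factory=dict)
    species_log2fc: dict[str, float] = field(default_factory=dict)
    gene_te_log2fc: dict[str, float] = field(default_factory=dict)
    codon_dwell: dict[str, float] = field(default_factory=dict)  # KO condition

    @property
    def m7g_ids(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.planted_sites)


@dataclass(frozen=True)
class Transcript:
    """A simulated mRNA: 5'UTR + CDS (ATG ... stop) + 3'UTR, 0-based half-open."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    def codons(self) -> list[str]:
        cds = self.cds
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]


# ---------------------------------------------------------------------------
# tRNA reference
# ---------------------------------------------------------------------------

def simulate_trna_reference(
    cfg: SimulationConfig,
) -> tuple[list[TRNASpecies], SyntheticTruth]:
    """Generate a tRNA reference with planted m7G variable-loop sites.

    Anticodons are sampled (without replacement) from the reverse
    complements of the sense codons, so every species has a distinct sense
    WC codon.  Exactly ``n_m7g`` species are flagged m7G; their 5-mer
    context at positions -3..+1 around the planted G is drawn from
    ``{A,G}AGGT``, the purine-led motif characteristic of tRNA position 46.
    Per-species abundance log2 fold changes in KO are planted here as well.
    """
    rng = _rng(cfg.seed, "trna_ref")
    anticodons = sorted(revcomp(c) for c in SENSE_CODONS)
    chosen = rng.choice(len(anticodons), size=cfg.n_trna_species, replace=False)
    chosen = sorted(chosen)
    # m7G planting leaves every synonymous family at least one unmodified
    # codon (and so skips single-codon Met/Trp decoders): every modified
    # codon keeps a synonymous alternative, which makes full recoding
    # feasible in principle and keeps the genome-wide modified-codon load
    # comparable across random references.
    order = rng.permutation(cfg.n_trna_species)
    m7g_idx: set[int] = set()
    planted_per_aa: dict[str, int] = {}
    for i in order:
        if len(m7g_idx) == cfg.n_m7g:
            break
        aa = CODON_TO_AA[wc_codon(anticodons[chosen[i]])]
        family = len(AA_TO_CODONS[aa])
        if planted_per_aa.get(aa, 0) + 1 >= family:
            continue
        m7g_idx.add(int(i))
        planted_per_aa[aa] = planted_per_aa.get(aa, 0) + 1
    if len(m7g_idx) < cfg.n_m7g:
        raise ValidationError("too few multi-codon-family species to plant n_m7g sites")
    site = cfg.variable_loop_site
    lo, hi = cfg.trna_len_range

    species: list[TRNASpecies] = []
    truth = SyntheticTruth()
    seen_seqs: set[str] = set()
    down_idx: set[int] | None = None
    if cfg.n_down_m7g is not None:
        order = sorted(m7g_idx)
        picked = rng.choice(len(order), size=cfg.n_down_m7g, replace=False)
        down_idx = {order[i] for i in picked}

    coupled_fc = None
    if cfg.couple_dwell_to_abundance:
        a, b = cfg.coupled_log2fc_range
        coupled_fc = rng.uniform(a, b, size=cfg.n_m7g)

    m7g_counter = 0
    for i, ai in enumerate(chosen):
        anticodon = anticodons[ai]
        codon = wc_codon(anticodon)
        aa = CODON_TO_AA[codon]
        sid = f"{aa}-{anticodon}"
        is_m7g = i in m7g_idx
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = list(rng.choice(_BASES, size=length))
            seq[33:36] = list(anticodon)  # anticodon at positions 34-36 (1-based)
            if is_m7g:
                context = str(rng.choice(["A", "G"])) + "AGGT"
                seq[site - 3 : site + 2] = list(context)
            s = "".join(seq)
            if s not in seen_seqs:
                seen_seqs.add(s)
                break
        species.append(
            TRNASpecies(
                id=sid,
                amino_acid=aa,
                anticodon=anticodon,
                sequence=s,
                variable_loop_site=site,
                is_m7g=is_m7g,
            )
        )
        if is_m7g:
            truth.planted_sites.append((sid, site))
            truth.planted_contexts[sid] = s[site - 3 : site + 2]
            if coupled_fc is not None:
                truth.species_log2fc[sid] = float(coupled_fc[m7g_counter])
            elif down_idx is not None:
                truth.species_log2fc[sid] = cfg.trna_fc if i in down_idx else 0.0
            else:
                truth.species_log2fc[sid] = cfg.trna_fc
            m7g_counter += 1
        else:
            truth.species_log2fc[sid] = 0.0
    return species, truth


# ---------------------------------------------------------------------------
# TRAC-seq read simulation
# ---------------------------------------------------------------------------

def _fragment(seq: str, cuts: Sequence[int], min_len: int) -> list[str]:
    """Cut ``seq`` at each position in ``cuts``, losing the cut base."""
    frags = []
    prev = 0
    for c in sorted(cuts):
        if c - prev >= min_len:
            frags.append(seq[prev:c])
        prev = c + 1
    if len(seq) - prev >= min_len:
        frags.append(seq[prev:])
    return frags


def simulate_tracseq_reads(
    reference: Sequence[TRNASpecies],
    truth: SyntheticTruth,
    cfg: SimulationConfig,
) -> tuple[list[str], list[str]]:
    """Simulate treated and input TRAC-seq libraries.

    Each library samples ``tracseq_depth`` tRNA molecules uniformly across
    species.  In the treated library a molecule of an m7G species is cleaved
    at its planted site with probability ``p_cleave``; every covered G is
    additionally cleaved with probability ``p_bg`` in both libraries.  The
    cleaved base itself is lost.  Fragments shorter than
    ``min_fragment_len`` are dropped (unalignably short).
    """
    if not reference:
        raise ValidationError("reference is empty")
    out: dict[str, list[str]] = {}
    for library in ("treated", "input"):
        rng = _rng(cfg.seed, "tracseq", library)
        reads: list[str] = []
        n_per_species = rng.multinomial(
            cfg.tracseq_depth, np.full(len(reference), 1.0 / len(reference))
        )
        for sp, n in zip(reference, n_per_species):
            seq = sp.sequence
            g_pos = np.array([i for i, b in enumerate(seq) if b == "G"])
            bg = rng.random((n, g_pos.size)) < cfg.p_bg
            planted = (
                rng.random(n) < cfg.p_cleave
                if (library == "treated" and sp.is_m7g)
                else np.zeros(n, dtype=bool)
            )
            any_cut = bg.any(axis=1) | planted
            n_intact = int(n - any_cut.sum())
            reads.extend([seq] * n_intact)
            site = sp.variable_loop_site
            for row in np.nonzero(any_cut)[0]:
                cuts = set(g_pos[bg[row]].tolist())
                if planted[row]:
                    cuts.add(site)
                reads.extend(_fragment(seq, sorted(cuts), cfg.min_fragment_len))
        out[library] = reads
    return out["treated"], out["input"]


def count_site_cleavage(
    reads: Iterable[str], species: TRNASpecies, site: int
) -> tuple[int, int]:
    """Counting oracle: (molecules cleaved at ``site``, molecules reading through).

    A molecule cleaved at the site leaves a 5' fragment ending at
    ``site - 1``; a read-through molecule leaves a fragment containing the
    site base.  Counts rely on exact substring placement in the species
    sequence, independent of the pipeline's aligner.
    """
    seq = species.sequence
    n_end = n_span = 0
    for r in reads:
        p = seq.find(r)
        if p < 0:
            continue
        if p + len(r) == site:
            n_end += 1
        elif p <= site < p + len(r):
            n_span += 1
    return n_end, n_span


# ---------------------------------------------------------------------------
# tRNA abundance count libraries
# ---------------------------------------------------------------------------

def simulate_trna_counts(
    reference: Sequence[TRNASpecies],
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    condition: Condition,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Species-level input-library read counts (species x replicates).

    Species are equimolar in CTRL; in KO each species' abundance is scaled
    by its planted ``2**log2fc``.  Counts are negative-binomial around the
    expected library share.
    """
    n_rep = n_replicates or cfg.n_replicates
    ids = [sp.id for sp in reference]
    w = np.array(
        [
            2.0 ** truth.species_log2fc.get(sid, 0.0) if condition == "KO" else 1.0
            for sid in ids
        ]
    )
    mean = cfg.tracseq_depth * w / w.sum()
    cols = {}
    for rep in range(1, n_rep + 1):
        rng = _rng(cfg.seed, "trna_counts", condition, rep)
        cols[f"rep{rep}"] = _nb(rng, mean, cfg.nb_dispersion)
    return pd.DataFrame(cols, index=pd.Index(ids, name="species"))


def _nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance mu + phi * mu^2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def simulate_transcriptome(
    cfg: SimulationConfig, class_map: CodonClassMap | None = None
) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate ``n_genes`` transcripts with 5'UTR, CDS and 3'UTR.

    Amino acids are sampled uniformly.  Within each synonymous family,
    every M7G_DECODED codon takes a fixed ``m7g_codon_share`` of the
    family's usage and the remaining codons split the rest uniformly
    (uniform usage when no class map is given).  Pinning the share, rather
    than a fixed weight, makes the genome-wide m7G-codon load independent
    of how the random m7G set distributes over family sizes.  CDSs start
    with ATG, end with a stop codon and contain no internal stop by
    construction.
    """
    rng = _rng(cfg.seed, "transcriptome")
    aa_of = np.array([CODON_TO_AA[c] for c in SENSE_CODONS])
    probs = np.zeros(len(SENSE_CODONS))
    s = cfg.m7g_codon_share
    for aa in np.unique(aa_of):
        fam = np.nonzero(aa_of == aa)[0]
        k = fam.size
        is_m7g = np.array(
            [
                class_map is not None
                and class_map[SENSE_CODONS[i]] is CodonClass.M7G_DECODED
                for i in fam
            ]
        )
        j = int(is_m7g.sum())
        if 0 < j < k and j * s < 1:
            probs[fam[is_m7g]] = s
            probs[fam[~is_m7g]] = (1 - j * s) / (k - j)
        else:  # no modified codon, or degenerate family: uniform
            probs[fam] = 1.0 / k
    probs /= len(np.unique(aa_of))
    probs /= probs.sum()

    codon_arr = np.array(SENSE_CODONS)
    lo, hi = cfg.cds_length_range
    transcripts: list[Transcript] = []
    rows = []
    for g in range(cfg.n_genes):
        ncod = int(rng.integers(lo, hi + 1))
        body = codon_arr[rng.choice(len(SENSE_CODONS), size=ncod, p=probs)]
        stop = str(rng.choice(STOP_CODONS))
        utr5 = "".join(rng.choice(_BASES, size=cfg.utr5_len))
        utr3 = "".join(rng.choice(_BASES, size=cfg.utr3_len))
        cds = "ATG" + "".join(body) + stop
        seq = utr5 + cds + utr3
        tid = f"g{g:04d}"
        transcripts.append(
            Transcript(
                id=tid,
                sequence=seq,
                cds_start=cfg.utr5_len,
                cds_end=cfg.utr5_len + len(cds),
            )
        )
        rows.append((tid, cfg.utr5_len, cfg.utr5_len + len(cds), len(seq)))
    annotation = pd.DataFrame(
        rows, columns=["transcript", "cds_start", "cds_end", "length"]
    )
    return transcripts, annotation


# ---------------------------------------------------------------------------
# Ribo-seq footprints and RNA/RPF count tables
# ---------------------------------------------------------------------------

def _gene_params(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Condition-independent gene-level truth: expression, baseline TE,
    indices of genes with a planted TE shift."""
    rng = _rng(cfg.seed, "genes")
    lam = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base_te = 2.0 ** rng.normal(0.0, 0.25, size=cfg.n_genes)
    n_eff = int(round(cfg.te_effect_genes * cfg.n_genes))
    effect = rng.choice(cfg.n_genes, size=n_eff, replace=False)
    return lam, base_te, np.sort(effect)


def _codon_dwell(
    cfg: SimulationConfig,
    class_map: CodonClassMap,
    condition: Condition,
    truth: SyntheticTruth | None,
    decoding_table: CodonDecodingTable | None,
) -> dict[str, float]:
    """KO dwell multiplier per codon (1.0 everywhere in CTRL)."""
    dwell = {c: 1.0 for c in SENSE_CODONS}
    if condition != "KO":
        return dwell
    for c in SENSE_CODONS:
        if class_map[c] is not CodonClass.M7G_DECODED:
            continue
        if (
            cfg.couple_dwell_to_abundance
            and truth is not None
            and decoding_table is not None
        ):
            fcs = [
                truth.species_log2fc[s]
                for s in decoding_table.wc_cognates[c]
                if s in truth.m7g_ids
            ]
            dwell[c] = 2.0 ** (-float(np.mean(fcs))) if fcs else cfg.pause_factor
        else:
            dwell[c] = cfg.pause_factor
    return dwell


def simulate_ribo_rna(
    transcripts: Sequence[Transcript],
    class_map: CodonClassMap,
    cfg: SimulationConfig,
    condition: Condition,
    truth: SyntheticTruth | None = None,
    decoding_table: CodonDecodingTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate footprints plus gene-level RNA and RPF count tables.

    Footprints: ``cds_fraction`` of them have their A-site at a CDS codon,
    sampled proportional to gene expression x TE x codon dwell weight; the
    rest sit uniformly in the UTRs.  The 5' start is ``A-site nt -
    offset[length]`` with the shared offset table, so the analyser's
    assignment inverts the construction exactly.

    Counts: per-gene negative-binomial replicates; RNA means follow
    expression, RPF means follow expression x TE, with the planted TE shift
    applied in KO.  Returns ``(footprints, rna_counts, rpf_counts)``.
    """
    if condition not in ("CTRL", "KO"):
        raise ValidationError(f"unknown condition {condition!r}")
    lam, base_te, effect = _gene_params(cfg)
    te = base_te.copy()
    if condition == "KO":
        te[effect] *= 2.0 ** cfg.te_effect_size
    dwell = _codon_dwell(cfg, class_map, condition, truth, decoding_table)
    if truth is not None:
        truth.codon_dwell = dict(dwell)
        for gi, t in enumerate(transcripts):
            truth.gene_te_log2fc[t.id] = (
                cfg.te_effect_size if gi in effect else 0.0
            )

    rng = _rng(cfg.seed, "ribo", condition)
    # --- flatten codon instances across all transcripts ---
    t_idx_parts, codon_idx_parts, weight_parts = [], [], []
    for gi, t in enumerate(transcripts):
        w = np.array([dwell.get(c, 1.0) for c in t.codons()])
        t_idx_parts.append(np.full(w.size, gi))
        codon_idx_parts.append(np.arange(w.size))
        weight_parts.append(w * lam[gi] * te[gi])
    t_idx = np.concatenate(t_idx_parts)
    codon_idx = np.concatenate(codon_idx_parts)
    weight = np.concatenate(weight_parts)

    n_cds = int(round(cfg.ribo_depth * cfg.cds_fraction))
    n_utr = cfg.ribo_depth - n_cds
    counts = rng.multinomial(n_cds, weight / weight.sum())
    hit = np.repeat(np.arange(weight.size), counts)
    lengths_cds = _FOOTPRINT_LENGTHS[
        rng.choice(_FOOTPRINT_LENGTHS.size, size=n_cds, p=_FOOTPRINT_LENGTH_PROBS)
    ]
    offsets = np.array([DEFAULT_OFFSETS[l] for l in _FOOTPRINT_LENGTHS])
    off_of = dict(zip(_FOOTPRINT_LENGTHS.tolist(), offsets.tolist()))
    cds_start_arr = np.array([t.cds_start for t in transcripts])
    a_nt = cds_start_arr[t_idx[hit]] + 3 * codon_idx[hit]
    start_cds = a_nt - np.vectorize(off_of.get)(lengths_cds)
    fp_t = [t_idx[hit]]
    fp_start = [start_cds]
    fp_len = [lengths_cds]

    if n_utr > 0:
        gene_w = lam * te
        g = rng.choice(len(transcripts), size=n_utr, p=gene_w / gene_w.sum())
        lengths_utr = _FOOTPRINT_LENGTHS[
            rng.choice(_FOOTPRINT_LENGTHS.size, size=n_utr, p=_FOOTPRINT_LENGTH_PROBS)
        ]
        max_off = max(DEFAULT_OFFSETS.values())
        utr5_w = cfg.utr5_len - max_off
        cds_end_arr = np.array([t.cds_end for t in transcripts])
        tlen_arr = np.array([len(t.sequence) for t in transcripts])
        utr3_w = tlen_arr[g] - max_off - cds_end_arr[g]
        in5 = rng.random(n_utr) < utr5_w / (utr5_w + utr3_w)
        a5 = rng.integers(max_off, cfg.utr5_len, size=n_utr)
        a3 = cds_end_arr[g] + rng.integers(0, np.maximum(utr3_w, 1))
        a_utr = np.where(in5, a5, a3)
        start_utr = a_utr - np.vectorize(off_of.get)(lengths_utr)
        fp_t.append(g)
        fp_start.append(start_utr)
        fp_len.append(lengths_utr)

    ids = np.array([t.id for t in transcripts])
    footprints = pd.DataFrame(
        {
            "transcript": ids[np.concatenate(fp_t)],
            "start": np.concatenate(fp_start).astype(int),
            "length": np.concatenate(fp_len).astype(int),
        }
    )

    rna_mean = cfg.rna_depth * lam / lam.sum()
    rpf_w = lam * te
    rpf_mean = cfg.ribo_depth * rpf_w / rpf_w.sum()
    rna_cols, rpf_cols = {}, {}
    for rep in range(1, cfg.n_replicates + 1):
        r1 = _rng(cfg.seed, "rna_counts", condition, rep)
        r2 = _rng(cfg.seed, "rpf_counts", condition, rep)
        rna_cols[f"rep{rep}"] = _nb(r1, rna_mean, cfg.nb_dispersion)
        rpf_cols[f"rep{rep}"] = _nb(r2, rpf_mean, cfg.nb_dispersion)
    index = pd.Index(ids, name="gene")
    return (
        footprints,
        pd.DataFrame(rna_cols, index=index),
        pd.DataFrame(rpf_cols, index=index),
    )


def class_instance_fraction(
    transcripts: Sequence[Transcript], class_map: CodonClassMap
) -> dict[CodonClass, float]:
    """Fraction of CDS codon instances per class (expectation oracle input)."""
    counts = {cls: 0 for cls in CodonClass}
    total = 0
    for t in transcripts:
        for c in t.codons():
            if c in CODON_TO_AA:
                counts[class_map[c]] += 1
                total += 1
    return {cls: n / total for cls, n in counts.items()}


def dwell_by_class(
    footprints: pd.DataFrame,
    transcripts: Sequence[Transcript],
    class_map: CodonClassMap,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> dict[CodonClass, float]:
    """Counting oracle: mean footprint count per codon instance, by class,
    normalised to the overall per-instance mean.  Reads the raw simulated
    records directly (planted starts/lengths), not the pipeline's assigner.
    """
    by_t = {t.id: t for t in transcripts}
    per_class_counts = {cls: 0.0 for cls in CodonClass}
    a_nt = footprints["start"].to_numpy() + footprints["length"].map(offsets).to_numpy()
    df = pd.DataFrame({"transcript": footprints["transcript"].to_numpy(), "a": a_nt})
    for tid, grp in df.groupby("transcript", sort=False):
        t = by_t[tid]
        a = grp["a"].to_numpy()
        a = a[(a >= t.cds_start) & (a < t.cds_end)]
        codon_classes = np.array(
            [
                class_map[c].value if c in CODON_TO_AA else "stop"
                for c in t.codons()
            ]
        )
        hit_cls = codon_classes[(a - t.cds_start) // 3]
        for cls in CodonClass:
            per_class_counts[cls] += int((hit_cls == cls.value).sum())
    frac = class_instance_fraction(transcripts, class_map)
    total = sum(per_class_counts.values())
    n_inst = sum(len([c for c in t.codons() if c in CODON_TO_AA]) for t in transcripts)
    overall = total / n_inst
    return {
        cls: (per_class_counts[cls] / (frac[cls] * n_inst)) / overall
        for cls in CodonClass
        if frac[cls] > 0
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_log2fc: float,
    ct_noise_sd: float,
    seed: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table (target/reference x treated/control, replicates).

    Constructed so the noise-free delta-delta-Ct equals ``-true_log2fc``,
    i.e. the 2^(-ddCt) relative expression inverts exactly to
    ``2**true_log2fc``.
    """
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be >= 0")
    rng = _rng(seed, "qpcr")
    base = {
        ("target", "control"): 25.0,
        ("target", "treated"): 25.0 - true_log2fc,
        ("reference", "control"): 20.0,
        ("reference", "treated"): 20.0,
    }
    rows = []
    for (gene, condition), ct in base.items():
        noise = rng.normal(0.0, ct_noise_sd, size=n_replicates) if ct_noise_sd else np.zeros(n_replicates)
        for rep in range(n_replicates):
            rows.append((gene, condition, rep + 1, ct + noise[rep]))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
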