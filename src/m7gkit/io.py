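"""Shared readers and writers.

Conventions: FASTA for sequences (wrapped or unwrapped accepted, sequences
uppercased on read); TSV with headers for tables; BED6 for footprints in
transcript coordinates (0-based half-open, strand '+'); positions are
0-based in files and 1-based only in human-readable report columns that say
so in their header.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codonopt import CDSRecord
from .simulate import Transcript
from .tracseq import M7GSiteCall
from .trna import CodonClass, CodonClassMap, TRNASpecies, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_trna_reference",
    "write_trna_reference",
    "read_class_map",
    "write_class_map",
    "read_counts",
    "write_counts",
    "read_footprints_bed",
    "write_footprints_bed",
    "read_transcripts",
    "write_transcripts",
    "write_calls",
    "read_calls",
    "file_sha256",
]


def read_fasta(path: "str | Path") -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); sequences are uppercased."""
    path = Path(path)
    records = []
    had_lower = False
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            if seq != seq.upper():
                had_lower = True
            records.append((rec.id, seq.upper()))
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed FASTA ({exc})") from exc
    if not records and path.stat().st_size > 0:
        raise ValidationError(f"{path}: no FASTA records (missing '>' header?)")
    if had_lower:
        logger.info("%s: lowercase sequence uppercased", path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: "str | Path", wrap: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(seqrecords)


def write_trna_reference(
    species: Sequence[TRNASpecies], fasta_path: "str | Path", sidecar_path: "str | Path"
) -> None:
    """tRNA reference = FASTA + sidecar TSV with annotation columns."""
    write_fasta([(sp.id, sp.sequence) for sp in species], fasta_path)
    pd.DataFrame(
        {
            "id": [sp.id for sp in species],
            "amino_acid": [sp.amino_acid for sp in species],
            "anticodon": [sp.anticodon for sp in species],
            "variable_loop_site": [sp.variable_loop_site for sp in species],
            "is_m7g": [int(sp.is_m7g) for sp in species],
        }
    ).to_csv(sidecar_path, sep="\t", index=False)


def read_trna_reference(
    fasta_path: "str | Path", sidecar_path: "str | Path"
) -> list[TRNASpecies]:
    seqs = dict(read_fasta(fasta_path))
    meta = pd.read_csv(sidecar_path, sep="\t")
    species = []
    for row in meta.itertuples(index=False):
        if row.id not in seqs:
            raise ValidationError(f"{row.id} in sidecar but not in FASTA")
        species.append(
            TRNASpecies(
                id=row.id,
                amino_acid=row.amino_acid,
                anticodon=row.anticodon,
                sequence=seqs[row.id],
                variable_loop_site=int(row.variable_loop_site),
                is_m7g=bool(row.is_m7g),
            )
        )
    return species


def write_class_map(class_map: CodonClassMap, path: "str | Path") -> None:
    pd.DataFrame(
        {"codon": list(class_map.class_of), "codon_class": [str(v) for v in class_map.class_of.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_class_map(path: "str | Path") -> CodonClassMap:
    df = pd.read_csv(path, sep="\t")
    return CodonClassMap(
        class_of={r.codon: CodonClass(r.codon_class) for r in df.itertuples(index=False)}
    )


def write_counts(counts: pd.DataFrame, path: "str | Path") -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_footprints_bed(footprints: pd.DataFrame, path: "str | Path") -> None:
    """Footprints as BED6: transcript, start, end (0-based half-open), '+'."""
    bed = pd.DataFrame(
        {
            "chrom": footprints["transcript"],
            "start": footprints["start"],
            "end": footprints["start"] + footprints["length"],
            "name": "fp",
            "score": 0,
            "strand": "+",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_footprints_bed(path: "str | Path") -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "transcript": bed["chrom"],
            "start": bed["start"].astype(int),
            "length": (bed["end"] - bed["start"]).astype(int),
        }
    )


def write_transcripts(
    transcripts: Sequence[Transcript],
    fasta_path: "str | Path",
    annotation_path: "str | Path",
) -> None:
    write_fasta([(t.id, t.sequence) for t in transcripts], fasta_path)
    pd.DataFrame(
        {
            "transcript": [t.id for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "length": [len(t.sequence) for t in transcripts],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


def read_transcripts(
    fasta_path: "str | Path", annotation_path: "str | Path"
) -> list[Transcript]:
    seqs = dict(read_fasta(fasta_path))
    ann = pd.read_csv(annotation_path, sep="\t")
    out = []
    for row in ann.itertuples(index=False):
        if row.transcript not in seqs:
            raise ValidationError(f"{row.transcript} in annotation but not in FASTA")
        out.append(
            Transcript(
                id=row.transcript,
                sequence=seqs[row.transcript],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return out


def read_cds_fasta(path: "str | Path") -> list[CDSRecord]:
    return [CDSRecord(id=rid, sequence=seq) for rid, seq in read_fasta(path)]


def write_calls(calls: Sequence[M7GSiteCall], path: "str | Path") -> None:
    """Site calls as TSV; position_1based is the report-facing coordinate."""
    pd.DataFrame(
        {
            "species": [c.species_id for c in calls],
            "position_1based": [c.position + 1 for c in calls],
            "score": [c.score for c in calls],
            "coverage": [c.coverage for c in calls],
            "qvalue": [c.q_value for c in calls],
            "context": [c.context for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: "str | Path") -> list[M7GSiteCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        M7GSiteCall(
            species_id=r.species,
            position=int(r.position_1based) - 1,
            score=float(r.score),
            coverage=float(r.coverage),
            q_value=float(r.qvalue),
            context=r.context,
        )
        for r in df.itertuples(index=False)
    ]


def file_sha256(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
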