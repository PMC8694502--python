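"""Pipeline driver: chains simulation, TRAC-seq calling, codon
classification, Ribo-seq occupancy, TE analysis and codon scoring.

Stages communicate through files only, so any stage can be re-run from the
outputs already in the run directory, and a run is reconstructible from its
manifest (full config echo + output checksums + per-stage record counts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .codonopt import CDSRecord, rank_genes_by_m7g_usage
from .riboseq import assign_a_site, codon_occupancy, metagene_distribution, occupancy_change
from .simulate import (
    SimulationConfig,
    simulate_ribo_rna,
    simulate_tracseq_reads,
    simulate_transcriptome,
    simulate_trna_counts,
    simulate_trna_reference,
)
from .tequant import compute_te, delta_te, fold_change_filter
from .tracseq import (
    EndCountProfile,
    align_small_rna,
    call_sites,
    compute_cleavage_score,
    extract_motif,
    quantify_trna_abundance,
)
from .trna import ValidationError, WobbleRuleSet, build_decoding_table, classify_codons

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "tracseq", "classify", "ribo", "te", "codon_score")
# downstream stages that cannot run when a stage is off and its files absent
_DEPENDENTS = {
    "simulate": ("tracseq", "classify", "ribo", "te", "codon_score"),
    "tracseq": ("classify",),
    "classify": ("ribo", "codon_score"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Stage toggles plus every stage's thresholds, echoed into the manifest."""

    out_dir: Path = Path("m7gkit_run")
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # TRAC-seq calling
    alpha: float = 0.01
    min_cov: float = 20
    call_threshold: float = 2.0
    call_fdr: float = 0.05
    # Ribo-seq occupancy
    min_transcript_rpf: float = 64
    min_occurrences: int = 100
    # TE
    te_pseudocount: float = 0.5
    te_log2_threshold: float = 0.5
    te_fdr: float = 0.05
    # RNA fold-change filter
    fc_threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        return cls(out_dir=Path(raw.pop("out_dir", "m7gkit_run")), sim=sim, stages=stages, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    species, truth = simulate_trna_reference(sim)
    mio.write_trna_reference(species, out / "trna.fasta", out / "trna.tsv")
    pd.DataFrame(
        {
            "species": [s for s, _ in truth.planted_sites],
            "position": [p for _, p in truth.planted_sites],
            "context": [truth.planted_contexts[s] for s, _ in truth.planted_sites],
        }
    ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    treated, inputlib = simulate_tracseq_reads(species, truth, sim)
    mio.write_fasta(
        ((f"t{i}", r) for i, r in enumerate(treated)), out / "tracseq_treated.fasta"
    )
    mio.write_fasta(
        ((f"i{i}", r) for i, r in enumerate(inputlib)), out / "tracseq_input.fasta"
    )
    for cond in ("CTRL", "KO"):
        mio.write_counts(
            simulate_trna_counts(species, truth, sim, cond), out / f"trna_counts_{cond}.tsv"
        )
    rules = WobbleRuleSet.default()
    table = build_decoding_table(species, rules)
    class_map = classify_codons(table, truth.m7g_ids)
    transcripts, _ = simulate_transcriptome(sim, class_map)
    mio.write_transcripts(transcripts, out / "transcripts.fasta", out / "annotation.tsv")
    for cond in ("CTRL", "KO"):
        fps, rna, rpf = simulate_ribo_rna(transcripts, class_map, sim, cond, truth=truth)
        mio.write_footprints_bed(fps, out / f"footprints_{cond}.bed")
        mio.write_counts(rna, out / f"rna_counts_{cond}.tsv")
        mio.write_counts(rpf, out / f"rpf_counts_{cond}.tsv")
    pd.DataFrame(
        {"gene": list(truth.gene_te_log2fc), "te_log2fc": list(truth.gene_te_log2fc.values())}
    ).to_csv(out / "truth_te.tsv", sep="\t", index=False)
    return {
        "n_trna_species": len(species),
        "n_planted_sites": len(truth.planted_sites),
        "n_treated_reads": len(treated),
        "n_input_reads": len(inputlib),
        "n_transcripts": len(transcripts),
    }


def _stage_tracseq(cfg: PipelineConfig, out: Path) -> dict:
    species = mio.read_trna_reference(out / "trna.fasta", out / "trna.tsv")
    treated = [s for _, s in mio.read_fasta(out / "tracseq_treated.fasta")]
    inputlib = [s for _, s in mio.read_fasta(out / "tracseq_input.fasta")]
    prof = EndCountProfile(
        treated=align_small_rna(treated, species, "treated"),
        input=align_small_rna(inputlib, species, "input"),
        lengths={sp.id: len(sp.sequence) for sp in species},
    )
    track = compute_cleavage_score(prof, alpha=cfg.alpha, min_cov=cfg.min_cov)
    calls = call_sites(track, species, threshold=cfg.call_threshold, fdr=cfg.call_fdr)
    mio.write_calls(calls, out / "m7g_calls.tsv")
    if calls:
        consensus, pfm = extract_motif(calls)
        pfm.to_csv(out / "motif_pfm.tsv", sep="\t")
        (out / "motif_consensus.txt").write_text(consensus + "\n")
    ko = mio.read_counts(out / "trna_counts_KO.tsv")
    ctrl = mio.read_counts(out / "trna_counts_CTRL.tsv")
    quantify_trna_abundance(ko, ctrl).to_csv(out / "trna_abundance.tsv", sep="\t")
    return {
        "n_reads": prof.treated.n_reads + prof.input.n_reads,
        "n_unaligned": prof.treated.n_unaligned + prof.input.n_unaligned,
        "n_calls": len(calls),
    }


def _stage_classify(cfg: PipelineConfig, out: Path) -> dict:
    species = mio.read_trna_reference(out / "trna.fasta", out / "trna.tsv")
    calls_path = out / "m7g_calls.tsv"
    if calls_path.exists():
        m7g_ids = {c.species_id for c in mio.read_calls(calls_path)}
    else:  # fall back to the reference annotation
        m7g_ids = {sp.id for sp in species if sp.is_m7g}
    table = build_decoding_table(species, WobbleRuleSet.default())
    class_map = classify_codons(table, m7g_ids)
    mio.write_class_map(class_map, out / "codon_classes.tsv")
    return {"n_m7g_species": len(m7g_ids)}


def _stage_ribo(cfg: PipelineConfig, out: Path) -> dict:
    transcripts = mio.read_transcripts(out / "transcripts.fasta", out / "annotation.tsv")
    class_map = mio.read_class_map(out / "codon_classes.tsv")
    tables = {}
    counts = {}
    for cond in ("CTRL", "KO"):
        fps = mio.read_footprints_bed(out / f"footprints_{cond}.bed")
        cc, st = assign_a_site(fps, transcripts)
        if not st.conserved:
            raise ValidationError(f"{cond}: footprint conservation check failed")
        meta = metagene_distribution(fps, transcripts)
        tables[cond] = codon_occupancy(
            cc, class_map, cfg.min_transcript_rpf, cfg.min_occurrences
        )
        tables[cond].to_csv(out / f"occupancy_{cond}.tsv", sep="\t")
        counts[cond] = {"n_footprints": st.n_input, "cds_fraction": round(meta.cds, 4)}
    codon_table, class_tests = occupancy_change(tables["KO"], tables["CTRL"])
    codon_table.to_csv(out / "occupancy_change.tsv", sep="\t")
    class_tests.to_csv(out / "occupancy_class_tests.tsv", sep="\t", index=False)
    return {**counts, "n_codons_compared": int(codon_table["ratio_a"].notna().sum())}


def _stage_te(cfg: PipelineConfig, out: Path) -> dict:
    te = {}
    for cond in ("CTRL", "KO"):
        rpf = mio.read_counts(out / f"rpf_counts_{cond}.tsv")
        rna = mio.read_counts(out / f"rna_counts_{cond}.tsv")
        te[cond] = compute_te(rpf, rna, pseudocount=cfg.te_pseudocount)
    result = delta_te(
        te["KO"], te["CTRL"], log2_threshold=cfg.te_log2_threshold, fdr=cfg.te_fdr
    )
    result.to_csv(out / "te_results.tsv", sep="\t")
    rna_ko = mio.read_counts(out / "rna_counts_KO.tsv")
    rna_ctrl = mio.read_counts(out / "rna_counts_CTRL.tsv")
    pc = cfg.te_pseudocount
    ratio = ((rna_ko / rna_ko.sum(0) * 1e6).mean(1) + pc) / (
        (rna_ctrl / rna_ctrl.sum(0) * 1e6).mean(1) + pc
    )
    up, down = fold_change_filter(ratio, cfg.fc_threshold)
    pd.DataFrame(
        {"gene": up + down, "direction": ["up"] * len(up) + ["down"] * len(down)}
    ).to_csv(out / "rna_degs.tsv", sep="\t", index=False)
    return {
        "n_te_down": int((result["te_class"] == "TE_down").sum()),
        "n_te_up": int((result["te_class"] == "TE_up").sum()),
        "n_rna_up": len(up),
        "n_rna_down": len(down),
    }


def _stage_codon_score(cfg: PipelineConfig, out: Path) -> dict:
    transcripts = mio.read_transcripts(out / "transcripts.fasta", out / "annotation.tsv")
    class_map = mio.read_class_map(out / "codon_classes.tsv")
    cds_list = [CDSRecord(id=t.id, sequence=t.cds) for t in transcripts]
    ranked = rank_genes_by_m7g_usage(cds_list, class_map)
    ranked.to_csv(out / "m7g_usage_ranking.tsv", sep="\t", index=False)
    return {"n_genes_ranked": len(ranked)}


_RUNNERS = {
    "simulate": _stage_simulate,
    "tracseq": _stage_tracseq,
    "classify": _stage_classify,
    "ribo": _stage_ribo,
    "te": _stage_te,
    "codon_score": _stage_codon_score,
}

_REQUIRED_FILES = {
    "tracseq": ("trna.fasta", "tracseq_treated.fasta", "tracseq_input.fasta"),
    "classify": ("trna.fasta", "trna.tsv"),
    "ribo": ("transcripts.fasta", "codon_classes.tsv", "footprints_CTRL.bed"),
    "te": ("rpf_counts_KO.tsv", "rna_counts_KO.tsv"),
    "codon_score": ("transcripts.fasta", "codon_classes.tsv"),
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; write and return the manifest.

    A fixed seed yields byte-identical outputs.  A stage whose inputs are
    missing (because its producer was toggled off and never ran) is skipped
    with an explicit manifest entry; a stage error aborts the run with the
    stage name, and the manifest marks the partial outputs stale.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "m7gkit",
        "config": cfg.to_dict(),
        "stages": {},
        "checksums": {},
        "complete": False,
    }
    t0 = time.time()
    try:
        for stage in STAGES:
            if not cfg.stages.get(stage, True):
                manifest["stages"][stage] = {"status": "disabled"}
                continue
            missing = [
                f for f in _REQUIRED_FILES.get(stage, ()) if not (out / f).exists()
            ]
            if missing:
                manifest["stages"][stage] = {
                    "status": "skipped",
                    "missing_inputs": missing,
                }
                logger.warning("stage %s skipped: missing %s", stage, missing)
                continue
            logger.info("running stage %s", stage)
            try:
                counts = _RUNNERS[stage](cfg, out)
            except Exception as exc:
                manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise PipelineError(stage, exc) from exc
            manifest["stages"][stage] = {"status": "ok", "counts": counts}
        manifest["complete"] = True
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")) + sorted(
            out.glob("*.bed")
        ):
            manifest["checksums"][f.name] = mio.file_sha256(f)
        _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
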