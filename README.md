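# m7gkit

Desk-scale analysis of **N7-methylguanosine (m7G) tRNA modification** and its
consequences for translation.

In human cells the METTL1/WDR4 methyltransferase complex installs m7G at
position 46 in the variable loop of a specific subset of tRNAs. Losing the
modification destabilises those tRNAs; ribosomes then pause at the codons
they decode, and transcripts enriched in such codons are translated less
efficiently. m7gkit implements the computational chain that links these
layers of evidence:

1. **TRAC-seq site calling** — chemical reduction + aniline scission cleaves
   the tRNA backbone at m7G, so modified positions appear as site-specific
   read ends in a treated library but not in the matched input. Per position
   *m*, with cleavage evidence *E(m)* = reads ending at *m−1* plus reads
   starting at *m+1* and read-through coverage *C(m)*,

       f(m) = E(m) / (E(m) + C(m)),   score(m) = log2[(f_trt + α)/(f_inp + α)]

   A site is called when the base is G, score ≥ 2, and the BH-corrected
   two-library proportion test has q ≤ 0.05 (one site per tRNA, matching the
   single variable-loop site). Called-site contexts yield an IUPAC consensus
   motif and position frequency matrix.
2. **Codon classification** — each tRNA's anticodon is mapped to its
   Watson–Crick codon (reverse complement) and, through configurable wobble
   rules at anticodon position 34 (G34→{C,T}, U34→{A,G}, C34→{G}, A34 as
   inosine →{U,C,A}), the 61 sense codons are partitioned into
   `M7G_DECODED` / `WOBBLE_ONLY` / `NON_M7G`.
3. **Ribo-seq codon occupancy** — footprint 5′ ends plus a length-dependent
   offset give the A-site nucleotide; the pause score of a codon occurrence
   is its footprint count divided by the transcript's mean CDS count, so
   scores average 1 per transcript. Knockout/control ratios are compared
   between codon classes at the A site and at the A+1 control codon.
4. **Translation efficiency** — TE = (RPF CPM + c)/(RNA CPM + c) per gene,
   replicate-averaged in log space; genes are classified TE_down/TE_up by a
   moderated replicate test with BH correction. A plain two-fold-change
   filter produces RNA-level DEG lists, and 2^(−ΔΔCt) handles qPCR tables.
5. **Codon scoring and recoding** — genes are ranked by their fraction of
   m7G-decoded codons, and a designer builds synonymous mutants in which
   target codons are replaced by non-m7G-decoded synonyms (protein
   preserved), the construct used to test codon dependence experimentally.

Because the original sequencing datasets are not bundled, a first-class
**synthetic-data module** generates every input with planted ground truth —
cleavage sites with a purine-led `RAGGU` context, dwell-time multipliers at
m7G-decoded codons, negative-binomial RNA/RPF counts with planted TE shifts,
and qPCR Ct tables — so every estimator can be validated against what was
planted. All generators are pure functions of a seeded configuration.

## Worked example

```python
import m7gkit as m
from m7gkit.riboseq import assign_a_site, codon_occupancy, occupancy_change
from m7gkit.tracseq import (EndCountProfile, align_small_rna, call_sites,
                            compute_cleavage_score, extract_motif,
                            quantify_trna_abundance)

cfg = m.SimulationConfig(seed=1)                 # 40 tRNAs, 15 modified, 300 genes
species, truth = m.simulate_trna_reference(cfg)

# 1. TRAC-seq: call m7G sites from treated vs input cleavage
treated, inp = m.simulate_tracseq_reads(species, truth, cfg)
profile = EndCountProfile(
    treated=align_small_rna(treated, species, "treated"),
    input=align_small_rna(inp, species, "input"),
    lengths={sp.id: len(sp.sequence) for sp in species},
)
calls = call_sites(compute_cleavage_score(profile), species)
consensus, _ = extract_motif(calls, rna=True)

# 2. codon classes and the Ribo-seq A-site contrast (KO vs control)
table = m.build_decoding_table(species)
classes = m.classify_codons(table, {c.species_id for c in calls})
transcripts, _ = m.simulate_transcriptome(cfg, classes)
occ = {}
for cond in ("CTRL", "KO"):
    fps, _, _ = m.simulate_ribo_rna(transcripts, classes, cfg, cond)
    counts, _ = assign_a_site(fps, transcripts)
    occ[cond] = codon_occupancy(counts, classes)
codons, tests = occupancy_change(occ["KO"], occ["CTRL"], test="ranksum")

# 3. m7G-tRNA abundance change after knockout
abundance = quantify_trna_abundance(
    m.simulate_trna_counts(species, truth, cfg, "KO"),
    m.simulate_trna_counts(species, truth, cfg, "CTRL"),
)
```

Output of the full script (`seed=1`):

```
called 15 m7G sites; motif consensus RAGGU
example call: Ala-CGC position 46 score 5.05
M7G_DECODED  A-site ratio 1.89   A+1 ratio 1.00
NON_M7G      A-site ratio 0.94   A+1 ratio 1.00
class contrast: p = 1.6e-07 (A), 0.94 (A+1)
mean m7G-tRNA log2FC -0.97 (7 species flagged down)
```

Reading the numbers: all 15 planted m7G sites are recovered, each at
1-based position 46 (the variable loop), and the consensus over their 5-mer
contexts is `RAGGU`. With a planted two-fold dwell increase, the median
knockout/control occupancy ratio of m7G-decoded codons is ~1.9 at the A site
— slightly below 2 because pause scores are normalised by the transcript
mean, which the paused codons themselves inflate — while non-m7G codons and
the A+1 control stay near 1; only the A-site class contrast is significant.
The planted two-fold tRNA loss is estimated at log2FC ≈ −1.0; since that
sits exactly on the two-fold flagging threshold, about half the modified
species cross it, which is the expected behaviour for an effect at the
boundary.

## Command line

The same stages are available as subcommands of `m7gkit`:

```bash
m7gkit simulate --out-dir run --seed 1
m7gkit tracseq-call --treated run/tracseq_treated.fasta --input run/tracseq_input.fasta \
    --reference run/trna.fasta --sidecar run/trna.tsv --out run/calls.tsv
m7gkit classify-codons --reference run/trna.fasta --sidecar run/trna.tsv \
    --calls run/calls.tsv --out run/classes.tsv
m7gkit ribo-occupancy --footprints-ko run/footprints_KO.bed \
    --footprints-ctrl run/footprints_CTRL.bed --transcripts run/transcripts.fasta \
    --annotation run/annotation.tsv --classes run/classes.tsv --out run/occupancy
m7gkit te --rpf-ko run/rpf_counts_KO.tsv --rna-ko run/rna_counts_KO.tsv \
    --rpf-ctrl run/rpf_counts_CTRL.tsv --rna-ctrl run/rna_counts_CTRL.tsv --out run/te.tsv
m7gkit mutate-cds --cds cds.fasta --targets CCC,TAT --classes run/classes.tsv --out mut.fasta
m7gkit run-all --out-dir run --seed 1        # the whole chain, with a JSON manifest
```

`run-all` writes a manifest (config echo, per-stage record counts, output
checksums); a fixed seed reproduces every output byte for byte.

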