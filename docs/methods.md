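# Methods

This note documents the models behind m7gkit, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and statistical choices made where the design was open.

## The biological model

m7G46 is installed in the variable loop of a subset of tRNAs by the
METTL1/WDR4 methyltransferase. The pipeline operationalises three causal
links: (i) the modification is detectable as site-specific backbone
cleavage after chemical reduction/scission (treated library) relative to a
mock-treated input; (ii) loss of the modification lowers the abundance of
the affected tRNAs; (iii) scarce tRNAs slow decoding of their codons, seen
as elevated ribosome A-site occupancy and reduced translation efficiency of
codon-enriched transcripts.

## TRAC-seq cleavage scoring and site calling

Cleavage destroys the modified base: a cleaved molecule leaves a 5′
fragment ending at `site − 1` and a 3′ fragment starting at `site + 1`.
Cleavage evidence at position *m* is therefore `ends[m−1] + starts[m+1]`,
and read-through coverage is simply `coverage[m]` (a fragment containing
*m* was, by construction, not cleaved there). The per-library cleavage
fraction `f = E/(E + C)` and the score `log2((f_trt+α)/(f_inp+α))` follow.
The score is antisymmetric under swapping libraries and is masked where
either library has fewer than `min_cov` informative molecules.

Defaults: pseudofraction α = 0.01 (caps the score of zero-input positions
near log2(1/α) ≈ 6.6), `min_cov` = 20, call threshold 2.0 (a four-fold
cleavage-fraction enrichment), FDR 0.05 on a two-proportion z-test, one
site per tRNA (the biology admits a single variable-loop site; a flag
disables this for method comparison). Alignment is exact substring matching
with an edlib fallback at ≤1 substitution; a read matching *k* species
contributes weight 1/*k* to each, because tRNA isodecoders are
near-identical and discarding multi-mappers would zero their coverage.
Coordinates are 0-based internally and 1-based in report columns that say
so.

The motif is summarised over the called sites' 5-mer contexts (positions
−3..+1 around the site). Each consensus column is the smallest IUPAC set
reaching 90% summed frequency; a planted `{A,G}AGGT` context therefore
reads `RAGGT` (RNA rendering `RAGGU`).

## tRNA abundance quantification

Species-level counts per input library are CPM-normalised for reporting,
but inference runs on *mode-centred* log2 CPM: library depth is fixed, so
when a large minority of species drops (15 of 40 in the default knockout
design), total-count scaling shifts every log-ratio by the compositional
change, and even a DESeq-style median-of-ratios is contaminated because the
50th percentile falls at the edge of the unchanged cluster. Each library's
log2 CPM deviations from the across-library reference are re-centred on
the mean of their shortest half-sample (a mode estimate that locks onto
the unchanged-majority cluster and tolerates >1/3 one-sided change).

The replicate test contrasts conditions with a common variance pooled
across species; with three replicates a per-species Welch t-test (df ≈ 4)
is unstable enough that a chance high sample variance can mask a genuine
three-fold loss. Per-species Welch remains available
(`var_mode="welch"`). A species is flagged downregulated at
log2FC ≤ −1 and BH q ≤ 0.05 (both configurable).

## Codon decoding model

`wc_codon` is the reverse complement of the 5′→3′ anticodon (codon position
3 pairs anticodon position 34). Wobble rules default to G34→{C,T},
U34→{A,G}, C34→{G}, and A34 treated as inosine →{U,C,A}; every rule set
must contain the Watson–Crick partner, and a wobble cognate must differ
from the WC codon at position 3 (keeping the two cognate sets disjoint).
Codon classes: `WOBBLE_ONLY` when no WC cognate tRNA gene exists in the
reference set (gene presence is the reproducible proxy for "tRNA not
detected"), otherwise `M7G_DECODED` if any WC cognate is modified, else
`NON_M7G`. The modified set is always an input — an annotation or a
TRAC-seq call set — because it is cell-type specific.

## Ribo-seq occupancy

A-site offsets default to {26:14, 27:14, 28:15, 29:15, 30:16, 31:16} nt —
the standard convention for human 80S footprints — and the generator and
analyser share one table, so tests are convention-independent. The pause
score of a codon occurrence is its A-site footprint count divided by the
mean count over the transcript's CDS codons; scores average 1 per
transcript and are invariant to depth. Transcripts need ≥64 footprints and
codons ≥100 occurrences (per site) to enter the per-codon table; the
statistic is the mean over occurrences with the median reported alongside.
The A+1 table attributes each count to the codon one position 3′-ward: a
genuine decoding pause follows the A-site codon identity and vanishes at
A+1, which makes A+1 a within-gene negative control. (A one-nucleotide
rather than one-codon shift is not implemented; the codon-level control is
the conventional one.)

Because the normalising mean includes the paused codons themselves, a true
dwell factor *d* at a codon-instance fraction *f* yields expected class
ratios `d/(1+(d−1)f)` for the modified class and `1/(1+(d−1)f)` for the
rest; at the default design (*d* = 2, *f* ≈ 0.06) that is ≈1.89 and ≈0.94.

The class-level contrast (modified vs unmodified codons' KO/control
ratios, at A and A+1, BH across the two sites) defaults to **Welch's t on
log2 ratios**: the two classes have systematically different codon
occurrence counts, hence different ratio variances, and a rank-sum test
conflates that dispersion difference with a location shift (measured
per-replicate false-signal rate ~15% under the null, vs ~7% for Welch).
`test="ranksum"` selects the classical Wilcoxon rank-sum. Residual
mild anti-conservativeness of either test traces to a small positive
correlation between codon-level ratios (shared libraries and transcript
normalisation; measured variance inflation ≈1.3 on the class-mean
difference) — a known limitation of codon-level inference that
transcript-level resampling would remove at the cost of changing the
reported statistic.

The abundance–occupancy link pairs each modified codon's log2 A-site ratio
with the (cognate-mean) log2 abundance change of its modified WC cognates
and reports Spearman's ρ with an optional label-permutation null.
Degenerate inputs (constant columns) are flagged, not tested.

## Translation efficiency

TE = (RPF CPM + 0.5)/(RNA CPM + 0.5) per gene, replicate-averaged on the
log scale; CDS-length normalisation is optional because length cancels in
the knockout/control ratio. Genes are TE_down when log2ΔTE ≤ −0.5 with
BH q ≤ 0.05 (symmetrically TE_up). The 0.5 threshold intentionally sits
below the biologically interesting two-fold change: a threshold equal to
the expected effect size classifies at the boundary, where estimation noise
halves recall regardless of power. The replicate test pools a common
variance across genes (log-scale count noise is near-homoscedastic;
per-gene df = 4 at three replicates cannot reach corrected significance),
with per-gene Welch available. The RNA-level DEG filter is the plain
two-fold rule on normalised means; full negative-binomial differential
expression is out of scope. ΔΔCt is exact closed-form arithmetic:
`ΔΔCt = (Ct_t − Ct_ref)_treated − (Ct_t − Ct_ref)_control`, relative
expression `2^(−ΔΔCt)`; the polysome module ratios relative
polysome-bound level to relative input level per condition.

## Codon scoring and synonymous recoding

The gene score is the fraction of sense codons in the `M7G_DECODED` class.
The mutant designer replaces each target codon with the lexicographically
smallest synonymous `NON_M7G` codon — a deterministic tie-break chosen
because organism-specific codon-usage weights are deliberately out of
scope; supplying a decoding table restricts candidates to codons with at
least one cognate tRNA gene when possible. Targeting a codon whose amino
acid has no `NON_M7G` synonym (single-codon Met/Trp when modified) raises
an explicit unsatisfiable-design error. Translation invariance is asserted
on every design (standard genetic code, table 1).

## The synthetic-data generator

The generator's defaults define the study design; every generator is a
pure function of its seeded configuration, and each ships a counting or
expectation oracle that reads only the raw simulated records.

* **tRNA reference** — 40 species, 70–90 nt random bodies, anticodons
  sampled without replacement from sense-codon complements, candidate site
  fixed at index 45 (the Sprinzl-46 analogue). 15 species are modified,
  with 5-mer contexts drawn from `{A,G}AGGT`. Planting skips single-codon
  decoders and leaves every synonymous family at least one unmodified
  codon, so every modified codon keeps a synonymous alternative and the
  genome-wide modified-codon load does not depend on which family sizes
  the random set hits.
* **TRAC-seq** — 2×10⁵ molecules per library, equimolar species; treated
  molecules cleave at the planted site with probability 0.7, every covered
  G cleaves at 0.01 in both libraries, the cut base is lost, and fragments
  <15 nt are dropped (library-prep loss). The detectable cleavage fraction
  is then `p·s/(p·s + 1 − p)` with `s` the survival of the 5′-side
  fragment, which the oracle reproduces to <1σ.
* **Transcriptome** — 300 mRNAs, CDS 150–400 codons plus 50 nt UTRs,
  amino acids uniform; each modified codon takes a fixed 8% share of its
  family's usage (unmodified codons split the rest uniformly), putting the
  modified-codon load at ~6% of instances. Share, not weight, is pinned so
  that load is seed-stable.
* **Ribo-seq** — 5×10⁵ footprints per library, 85% with A-sites at CDS
  codons sampled proportional to expression × TE × dwell weight (dwell 2.0
  at modified codons in knockout; optionally `2^(−log2FC)` per cognate
  species when dwell is coupled to planted abundance loss), lengths 26–31
  peaked at 28, 5′ ends back-computed through the shared offset table.
* **Counts** — gene expression log-normal (σ = 1), baseline TE log-normal
  (σ_log2 = 0.25), negative binomial with variance μ + φμ² at φ = 0.01,
  typical of estimated dispersions for well-expressed genes in cell-line
  replicates and consistent with detecting two-fold TE shifts from three
  replicates; 10% of genes carry a −1 log2 TE shift in knockout. Count
  tables are drawn at gene level, independently of the footprint records,
  so codon-level and gene-level analyses can be validated separately.
* **qPCR** — Ct tables built so the noise-free ΔΔCt inverts exactly to the
  planted fold change, with Gaussian Ct noise (σ = 0.1 cycles).
* **Abundance** — knockout scales modified species by 2^(−1) by default;
  the selective scenario plants −1.5 on 14 of 20 modified species (a clear
  three-fold loss rather than an effect exactly at the flag threshold).

What the generator does **not** emulate: sequencing errors and adapters,
UMI/duplication structure, rRNA contamination, genome-space alignment and
splicing, initiation/termination peaks, uneven tRNA expression, real codon
usage bias, and correlated biological replicate structure. Passing tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to every artefact of real libraries.

## Determinism and numerics

Random streams derive from `(seed, stage-tag[, condition, replicate])`
through CRC-mixed NumPy `SeedSequence`s, so each generator is independent
of call order and byte-reproducible. Ratios guard zero denominators by
masking; scores are finite wherever coverage passes `min_cov`; BH
correction uses `scipy.stats.false_discovery_control`. ΔΔCt is bit-stable
at double precision (asserted to 1e−12). The pipeline driver runs stages
in dependency order, communicates only through files, checksums every
output into a JSON manifest, and marks skipped or failed stages
explicitly; re-running with the same seed reproduces identical checksums.

## Problem sizes

The default design (40 tRNAs, 2×10⁵ TRAC-seq reads, 300 genes, 5×10⁵
footprints and three replicates per condition) was chosen so that every
planted effect is detectable with comfortable statistical margin while a
full pipeline run completes in well under a minute on one CPU; the
20-replicate null control and the 1000-CDS recoding sweep each take tens
of seconds.

## Known limitations

* Codon-level class tests are mildly anti-conservative (see above); the
  20-replicate null-control check quantifies this and stays within its
  tolerance, but single null replicates can show q ≤ 0.05 at ~7% rate.
* The m7G species set used for classification comes from calls or
  annotation; no attempt is made to reconcile conflicting sources.
* Fractional multi-mapping assigns within-species placement to the first
  exact occurrence; repeated substrings within one tRNA body (vanishingly
  rare in random references, plausible in real isodecoders) would be
  mis-localised.
* The abundance normalisation assumes unchanged species form the largest
  tight cluster of log-ratios; designs where most species change would
  need spike-ins instead.
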