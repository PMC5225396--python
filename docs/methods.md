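# Methods

## Scope and data model

`lncduplex` operates downstream of read processing: its inputs are a genome
FASTA, a GTF annotation (known plus assembled transcripts), transcript-level
TPM with a sample→group map (case/control), per-method differential-expression
tables (gene id, linear fold change, FDR), BED tracks of Argonaute CLIP sites,
Alu elements and A-to-I editing positions, and mature miRNA FASTA. Read
trimming, mapping, assembly, quantification and the DE model fits themselves
are out of scope; only thresholding of the DE tables is performed. All inputs
are assumed to be on one assembly.

Internally every coordinate is 0-based half-open on the forward genomic
strand; GTF is converted on read, BED is native. Transcript space runs 5′→3′
of the transcript, so minus-strand transcript coordinates run against the
genomic direction; `transcript_to_genome` projects transcript-space intervals
(spliced or pre-mRNA) onto genomic blocks whose lengths always sum to the
interval length. All sequences are normalised to the DNA alphabet (U→T,
uppercase).

## lncRNA identification

Four criteria, all thresholds in `ScoringParams`:

* expression: max TPM over samples ≥ `min_tpm` (default 1.0; the boundary is
  inclusive);
* length: spliced length ≥ `min_lnc_length` (default 200 nt, inclusive);
* coding potential: longest open reading frame < `max_peptide_aa` (default
  100 aa; exactly 100 aa fails). The ORF definition is ATG-initiated,
  stop-terminated (the stop is required and not counted), scanned over the
  three forward frames only — appropriate for stranded RNA-Seq libraries.
  Codons containing N neither start nor stop an ORF but extend one as an
  unknown residue. Whether open-ended ORFs or six-frame scans should count is
  genuinely open; the forward-only, stop-required reading is this package's
  choice and is pinned by tests against a brute-force every-ATG oracle.
* biotype: transcripts whose Ensembl biotype belongs to the protein-coding or
  short-non-coding groups are excluded. The group membership is configurable;
  an absent/unknown biotype never matches an exclusion group, so novel
  transcripts fail open and are filtered by the structural rules instead.

Novel (assembled) transcripts must additionally have ≥ 2 exons and ≥ 200 nt,
and the ORF rule doubles as their coding/non-coding call; an external
per-transcript coding-verdict table can override it (`coding_verdict`).

## Duplex model and alignment

A duplex is an antiparallel intermolecular pairing. Rather than aligning the
lncRNA to the reverse complement of the target, the lncRNA is aligned to the
*reversed* target under a complementarity matrix (G:C = +4, A:T = +2, G:T
wobble = +1, everything else −6, including any column containing N) — the two
formulations are mathematically identical, and this one reports wobble pairs
naturally. Gap costs follow the affine convention in which a run of k gapped
bases costs |open| + k·|extend| = 20 + 8k, i.e. the first gapped base pays
both penalties.

Alignment is exact Smith–Waterman (a numba kernel; no seeding heuristics —
at these problem sizes exactness is affordable and simplifies the oracle
contract). Traceback tie-breaks are fixed (paired column ≻ gap in target ≻
gap in lncRNA) so output is deterministic. Alignments with score ≥
`min_score` (default 500) are emitted, applied per alignment, not per pair.
Sub-optimal duplexes are enumerated Waterman–Eggert style: the lncRNA and
target positions consumed by each reported alignment are masked and the
matrix re-run until nothing reaches the threshold, so the duplexes reported
for one pair never overlap on either sequence. N-containing columns score as
mismatches rather than being excluded; this makes deep-intron masking (below)
an effective hard barrier.

The search is database-style: lncRNAs against every transcript of a
differentially expressed gene (self-pairs skipped), in two spaces. In spliced
space the target is the mature transcript. In pre-mRNA space the target is
the unspliced locus with every intronic position farther than
`intron_margin` (default 250 nt) from both flanking splice sites masked to N;
introns of ≤ 2·margin stay fully unmasked. A duplex found in both spaces with
the same genomic blocks is the same physical pairing and is merged into one
interaction record (mechanism sets unioned), which keeps the interaction
table at one row per pairing per isoform.

## Mechanism classifiers

The "interaction region" is the union of the duplex's genomic blocks (an
`--span-region` switch uses the enclosing interval instead, since either
reading is defensible). All interval tests are half-open; intersections are
strand-agnostic by default, matching BEDTools-merge semantics (a `--stranded`
switch restricts all four classifiers to same-strand evidence).

* **Splicing modulation** (pre-mRNA duplexes only): the region must contain
  an exon–intron junction of the target in its interior — the junction point
  p counts as interior when both flanking bases p−1 and p are covered — and
  overlap at least one alternative splice site of the gene. A splice site is
  alternative when some isoform uses it and some isoform whose span contains
  it does not; this isoform-differential definition is this package's
  operationalisation of "alternative splicing event", which has no canonical
  single definition.
* **miRNA-site masking**: candidate sites come from a 7mer-m8 seed-match
  predictor (exact match of the reverse complement of miRNA positions 2–8,
  extended len(miRNA)−8 bases to the full putative pairing footprint). The
  seed predictor is a deliberately simple, fully specified stand-in for a
  full hybridisation-based site predictor; an external site list can be
  supplied instead. Predicted sites are intersected with merged Argonaute
  CLIP intervals — only the common part survives — and a site is masked when
  at least ⌈half_site_rule · site length⌉ of it lies inside the region
  (rounding up makes the boundary conservative and deterministic).
* **Editing triggering**: any single-base A-to-I position inside the region
  (half-open: a position at the region's end coordinate is outside).
* **Staufen-mediated decay**: an Alu interval entirely within the region and
  entirely within the target's 3′UTR (the spliced sequence past the last CDS
  base); targets without a CDS can never be SMD substrates.

The region classifier partitions every duplex: NONCODING (target has no CDS),
UTR (no CDS overlap), CDS (entirely within CDS), else UTR/CDS-overlapping.

## Cohort statistics

The DE gate passes a gene when FDR < `fdr_threshold` (strict, default 0.01)
and linear fold change ≥ `fc_threshold` or ≤ 1/`fc_threshold` (inclusive,
default 1.5); with several tables the default intersection mode requires all
of them to agree on direction (discordant genes are dropped with a warning),
and a union mode is available. The FDR-strict/FC-inclusive boundary reading
is a documented package choice — only "threshold" is specified upstream — and
both are configurable. Fold changes are case/control, so FC > 1 is up.

Condition-specific interactions keep a record when both partners have max
TPM ≥ `min_tpm` over case samples and < `min_tpm` over controls ("expressed"
reuses the 1-TPM convention). Mechanism summaries count unique lncRNAs per
mechanism (a lncRNA pairing with several splice isoforms of a gene counts
once), unique targets, region fractions, and a per-target mechanism-combination
breakdown: mechanisms are unioned over a target's records and the combination
shares are computed among targets with more than one mechanism. Overlap
concordance reports, among differentially expressed genes, how many gene
spans (min exon start to max exon end, strand-agnostic) overlap another DE
gene's span, the fraction of unordered overlapping pairs with the same
direction of change, and how many pairs contain a gene with a lncRNA isoform.
Gene-level and pair-level counts are reported separately since they answer
different questions.

## Synthetic cohort

The generator emits a complete input set with planted ground truth: 2
chromosomes × 100 kb of uniform random sequence; per mechanism (default 2
duplexes each, plus 1 SMD+editing combination) a two-isoform protein-coding
target gene and a two-exon lncRNA gene carrying the reverse complement of a
segment planted in the target's 3′UTR (miRNA/SMD/editing) or across an
alternative 3′ splice site in pre-mRNA (splicing); two idle lncRNAs (one on
the minus strand); two decoy lncRNAs per failure mode straddling each filter
boundary (TPM 0.9; 199 nt; exactly 100 aa; excluded biotype; single-exon
novel); supporting CLIP/Alu/editing evidence inside the planted footprints
and decoy intervals that violate each classifier's geometry; two overlapping
DE gene pairs (one concordant with a lncRNA isoform, one discordant); TPM for
5+5 samples with one case-only duplex pair per mechanism (case TPM ~ U(2,10),
control < 0.4); and two DE tables with passing genes (FDR ~ U(1e-6,1e-3),
FC ~ U(1.6,4)) plus decoys at each gate boundary (FC exactly 1.5, FDR exactly
0.01, FC 1.4, discordant directions).

Planted duplex segments are GC-rich (default 90% GC): under this matrix a
perfect pairing of uniform-composition RNA scores ≈ 3 per column, so
130–200-nt duplexes only clear the 500 threshold when GC-dense — as natural
Alu-derived duplex regions are. The generator tops up free A/T positions
until the perfect-pairing score exceeds the threshold with a safety margin,
caps the number of planted point mutations by that margin (each mismatch
costs at most 10), keeps mutations ≥ 8 nt from segment ends so recovered
footprints always cover the planted segment, and keeps planted evidence
≥ 14 nt inside the footprint. Before writing anything it re-aligns every
planted duplex, re-classifies every decoy lncRNA, and checks decoy-track
geometry ("full" validation additionally verifies no lncRNA reaches the
threshold against any non-partner target). All randomness flows from one
integer seed and regeneration is byte-identical.

What the synthetic cohort does *not* emulate: realistic transcriptome size
and base composition, repeat structure (planted "Alu" intervals are labelled
intervals, not Alu consensus sequence — the SMD classifier consumes
coordinates, not sequence), read-level noise, quantification uncertainty, and
genuinely ambiguous coding potential. Passing tests therefore demonstrate the
correctness of the algorithms and their boundary behaviour, not recall on
real corneal data.

## Numerical and engineering choices

* Problem sizes: the default synthetic cohort has ~34 genes / ~44 transcripts
  and a 200-kb genome, so a full pipeline run (including both alignment
  spaces) completes in seconds on one core while still exercising every
  branch; the acceptance script and the test suite use these sizes.
* The Smith–Waterman kernel and traceback are numba-compiled; the first call
  in a fresh environment pays a one-off JIT cost. Results are identical with
  JIT caching on or off, and thread counts never affect output.
* Determinism: output tables are sorted (catalog by transcript id, duplexes
  by score/coordinates, records by lncRNA/target/span); reruns are
  byte-identical except the timing log.
* Degenerate inputs: empty sequences align to nothing; single-exon
  transcripts have no introns to mask and no splice sites; merge of an empty
  interval list is empty; genes absent from DE tables are simply not scanned.
* Tests pin every rule with independent oracles: an exhaustive match-chaining
  enumerator for the aligner (no affine-gap state machine), an every-ATG
  walker for ORFs, and per-base position-set arithmetic for all five
  classifiers, plus boundary fixtures for each threshold (520/496 scores,
  250-nt masking, ⌈L/2⌉ half-site, one-base Alu overhang, FC/FDR/TPM/length/
  peptide boundaries).

## Known limitations

* The seed-match miRNA predictor reports no hybridisation energy and ignores
  non-canonical sites; it exists to provide site intervals for the masking
  rule, and real site lists can be substituted.
* Thermodynamic accessibility of the duplex partners is not modelled; scores
  measure complementarity, not hybridisation free energy.
* GFF3 input, liftOver/assembly conversion and BAM handling are out of scope;
  all inputs must share one assembly.
* The half-open junction-interior convention for splice-site coverage and the
  isoform-differential definition of alternative sites are documented choices;
  other operationalisations exist.
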