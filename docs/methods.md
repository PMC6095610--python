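# Methods

This note records the models, conventions, numerical choices and known
limitations behind chlororibo, in the order the pipeline runs.

## Coordinates and record model

Internal coordinates are 0-based half-open on the genomic plus strand;
written genomic reports are 1-based; GFF3 round-trips through 1-based
closed; bedGraph stays 0-based half-open. The biological 3′ end of an
alignment is `end − 1` on the plus strand and `start` on the minus strand.
Compartment (chloroplast vs nuclear) is resolved from the reference
sequence name through a configurable map; the pipeline consumes alignments
and takes no position on how they were produced. Overlapping ORFs are
handled by assigning each read independently to every overlapping gene.

A gene's **quantification segment** is the full CDS for single-exon genes
and the last exon (transcript orientation) for intron-containing genes,
with per-gene overrides expressed in the annotation layer (an exon number
or explicit interval) rather than hard-coded — the convention exists
because reads cannot be assigned confidently across unspliced organellar
intron transcripts. Reads spanning an exon–exon junction count toward a
segment only if their single assigned position lies inside it.

## Footprint geometry and P-site assignment

The package assumes the organellar-footprint property that fragments
translating the same codon share a similar 3′-end position regardless of
fragment length; the simulator realizes it exactly with a fixed
P-site-to-3′-end offset (`three_prime_offset`, default 15 nt). The
5′-to-P-site offset of an L-mer is therefore L − 16 (12 nt for the
canonical 28-mer).

`calibrate_offsets` recovers per-length offsets from the data: for each
length class it histograms the distance from 5′ ends to annotated start
codons. Ribosomes at codons 2, 3, … contribute distances 3, 6, … nt short
of the true offset, but no footprint originates upstream of the ORF, so
the offset is the largest distance still carrying substantial support (≥
30% of the histogram peak; stray non-CDS reads stay below that). Classes
with support below a floor (default 10 reads) fall back to the modal
(best-supported) offset; with no calibration signal at all the caller is
directed to a fixed-offset model (default 12 nt).

Assignment semantics are explicit everywhere: `three_prime_end` for
positional tracks, `p_site` (per-length calibrated) for steady-state
counting, `p_site_from_three_prime` (3′ end minus the fixed offset) where
a per-length model is unnecessary or the 3′-end convention must be
preserved (run-off body counts, CDS confinement), and `midpoint` for
RNA-seq. The exclusion windows are applied to the assigned position, not
by read overlap — overlap counting would make a 10-nt window effectively
length-dependent.

## Quantification

Ribo-seq RPKM counts reads whose assigned position lies in the
quantification segment minus its first 10 and last 30 nt (initiating and
terminating ribosomes), normalized per kb of segment and per million
nuclear-CDS reads. Length normalization uses the full segment length (a
switch selects the exclusion-trimmed length instead); the annotated length
keeps values comparable with per-gene tables quantified the usual way.
RNA-seq counts use the alignment midpoint anywhere in the CDS. Genes whose
eligible window is empty (< 41 nt) are flagged rather than counted. A
zero nuclear denominator is an error: the normalization is undefined.

## Synthetic data

The simulator's defaults are the study conditions the tests run under:

- **Toy plastome**: 10 genes of 600–1200 nt tiled alternately on both
  strands with 150-nt spacers; gene 0 is psbA; one gene carries a 150-nt
  intron with a short (~1/5 CDS) first exon so its quantified last exon
  lies within run-off reach on the time scales simulated.
- **Depth**: dark-baseline occupancy 6000 footprints/kb with per-gene
  multipliers log-uniform in [1/2, 2] — about 5 × 10⁴ chloroplast
  footprints per sample — over a nuclear background of exactly 10⁶ reads,
  so one read at a position ≈ 1 RpM, the scale at which the 30/50 RpM
  thresholds operate in real datasets.
- **Condition structure**: only psbA's ribosome occupancy scales with
  light (default ratio 6); RNA abundance is condition-independent
  (3000 reads/kb).
- **Footprints**: lengths categorical with mode 28 nt (the canonical
  elongating footprint length) for elongating ribosomes and mode 24 nt
  for initiation-mode ribosomes, matching the observed size-class
  contrast between start-region and body footprints under lincomycin;
  frame fidelity 0.9 (P-site jittered ±1 nt with probability 0.1).
- **Run-off**: deterministic front propagation — a gene's body codon c is
  occupied at time t iff c ≥ block + rate·t (block = 7 codons, the region
  lincomycin freezes) — with Poisson sampling of ribosome counts per
  codon. Elongation defaults: 5 codons/min light, 2.5 dark. These are
  effective rates of the front under asynchronous drug exposure, not
  literal per-ribosome velocities; an optional uniform per-chloroplast
  onset delay (off by default) smooths the front the same way
  asynchronous uptake would. Full exclusion-process dynamics (ribosome
  queuing) are deliberately out of scope: the analyses operate on
  occupancy expectations that queuing would perturb only near pause
  sites.
- **Start-region capture**: frozen initiators accumulate uniformly over
  the first 7 codons at 2 reads/min in the light vs 0.5 in the dark,
  giving the light-faster start-codon build-up the metagene trend reports.
- **Planted capture sites**: an ATG or GTG written into the sequence,
  preceded 5–13 nt upstream by the designed SD element, accumulating
  initiation-mode footprints at 12 reads/min in the light (~360 RpM by 30
  min — the few-hundred-RpM scale real build-up sites reach, and far
  enough above both the 50 RpM floor and 5-fold rule that recovery
  measures the caller, not Poisson luck). Auto-placement avoids psbA
  (whose light effect would confound the planted one) and the intron
  gene, and spaces same-host sites ≥ 12 codons apart so one site's SD
  cannot overwrite another's start codon. Capture rates are free
  simulator parameters scored against truth, not matched to any reported
  value.
- **Planted pause sites**: a per-codon dwell multiplier, optionally
  active in one condition only.
- **Determinism**: every sample derives its RNG stream from
  (seed, condition, assay, replicate, stage), so outputs are bit-identical
  for a fixed seed and independent across samples.

What the simulator does **not** model: sequence-dependent biases
(ligation, nuclease), multimapping and duplicates, rRNA contamination,
base quality, UTR translation, ribosome queuing, or biological replicate
overdispersion beyond Poisson. Passing recovery tests therefore shows the
analysis logic is correct under the stated statistical structure, not that
it is robust to library-preparation artifacts real data carry.

## Fold changes and pause comparison

Condition ratios are computed per replicate pair (paired by replicate
index) and summarized as mean ± SEM over replicates; a zero-denominator
replicate is dropped with a logged reason. Ribosome density ratios are the
per-replicate ribo/rna ratio quotients. Genes whose mRNA cannot be
measured confidently — ORFs < 150 nt and intron-containing genes — are
excluded from RNA and density ratios but keep their footprint ratio.

The pause comparison works on fractional occupancy (each position's share
of its ORF's reads), not raw RpM, so gene-level occupancy changes (psbA's
6-fold) cancel and only redistribution within the ORF registers. The
30-RpM floor discards a position only when it is below the floor in
*every* sample of a comparison; one-sided application would preferentially
keep positions that fluctuated high in one condition and bias toward
flagging (a switch selects the one-sided variant). Flagging requires a
> 2-fold (or < 0.5) change in ≥ 2 independent comparisons; with a single
comparison ratios are still reported but flagging is disabled. Each
comparison should be a replicate-pooled track pair: at single-replicate
depth the floor's selection effect plus Poisson noise produces borderline
false flags that pooling removes. No significance test is attached to
flagged sites — the rule is a reproducibility filter, not an inference.

## Run-off analysis

Build-up sites are called first; body counts then exclude the first 7
codons of the ORF (for intron genes quantified from a later exon the
segment may already start past them) and the called site positions,
shifted onto the implied-P-site coordinate the body count is taken in.
Curves are percent of the replicate-mean t=0 body RPKM; genes not above
100 RPKM at t=0 are reported but marked excluded, and zero-t=0 genes are
omitted. The clearance ratio is dark/light percent remaining at a chosen
time (default 30 min). The pipeline order — detection, exclusion, curves —
is deterministic; re-running reproduces outputs exactly.

## Build-up-site caller

A position qualifies when its replicate-mean light RpM at the final
timepoint reaches 50, its fold increase over t=0 reaches 5 (zero t=0 is
reported with an infinite-fold flag and excluded from ratio statistics,
and has no ratio-comparable matched control), and it is not attributable
to an annotated start region. The start-region exclusion operates on the
implied P-site (3′ end minus the fixed offset): a ribosome frozen at codon
7 leaves its 3′ end up to ~36 nt into the ORF, so excluding raw positions
within the first 21 nt would miss most start-frozen footprints. The
5-fold criterion is evaluated on light tracks (a switch widens it to
both conditions — the wording of the underlying convention is ambiguous).

Annotation searches for an ATG/GTG whose first base lies 9–18 nt upstream
of the footprint 3′ end (the implied P-site at 15 ± the spread real
initiation complexes show) and an SD element — ≥ 4 contiguous matches to
AGGAGG — ending 4–14 nt upstream of that codon. Among candidate codons
the one with the longest SD match wins, then proximity to the expected
spacing; frame is (implied P-site − CDS start) mod 3. Matched controls
minimize genomic distance subject to ≥ 500 nt separation, same strand,
and t=0 RpM within a factor of 2, widened ×1.5 until a candidate exists
(the final band is logged per site); the similarity band is this
package's operationalization of "similar read level", which has no
standard value.

## Thresholds

All thresholds live in `RunConfig` with these defaults: footprint lengths
18–40 nt; RPKM exclusion 10/30 nt; pause floor 30 RpM, 2-fold, ≥ 2
comparisons; build-up 50 RpM, 5-fold, 30 min; run-off t=0 filter 100
RPKM; block region 7 codons; minimum ORF 150 nt; control distance 500 nt;
SD ≥ 4 contiguous matches; start-codon window 9–18 nt; SD gap 4–14 nt;
3′ offset 15 nt; fallback P-site offset 12 nt. Stage code contains no
magic numbers; overrides are recorded in the run manifest.

## Problem sizes and test design

The test and acceptance runs use the simulator defaults above (10 genes,
~5 × 10⁴ chloroplast reads/sample, 3 steady-state replicates, 2 run-off
replicates at t = 0/12/30 min, 20 seeded runs of 10 planted capture sites
for caller sensitivity). The elongation analysis is cross-checked against
an independent single-ribosome stochastic walker at 4 × 10⁴ walkers per
gene, with agreement required within 3 combined (Monte-Carlo + counting)
standard errors. Fold-change recovery is asserted within
max(2·SEM, 5% of the true ratio): with 3 replicates the empirical SEM has
only 2 degrees of freedom and occasionally collapses near zero by chance,
so the deviation-over-SEM statistic is t₂-distributed and a pure 2·SEM
band would reject true recovery ~18% of the time per gene; the 5% floor
bounds that artifact while remaining far tighter than the 6-vs-1 effect
being detected. The pause-flagging check uses three independently
simulated regimes with uniform per-gene occupancy so the planted 3-fold
dwell is the only positional signal.

## Known limitations

- The exclusion windows, pause floor and caller thresholds are fixed
  conventions, not estimated from data; datasets at very different
  normalization depths need rescaled RpM thresholds.
- Offset calibration needs annotated start codons with local coverage;
  heavily 5′-biased or UTR-rich data would need the fixed-offset mode.
- The run-off model reads out an effective clearance rate; converting it
  to codons/min assumes synchronous drug onset, which wicking-type
  delivery does not guarantee — between-condition comparisons (the
  dark/light ratio) are the robust quantity.
- Multimapped reads are out of scope; the inverted-repeat regions of real
  plastomes would need upstream handling.
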