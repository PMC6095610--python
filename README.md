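# chlororibo

Analysis pipeline for chloroplast ribosome profiling (Ribo-seq), built for
studies of how light regulates plastid translation: per-gene footprint
quantification normalized to nuclear reads, light/dark comparisons of
ribosome occupancy and ribosome density, positional pause-site comparison,
translation-elongation-rate measurement from antibiotic run-off time
courses, and detection of ectopic ribosome build-up sites with
Shine-Dalgarno annotation. A synthetic footprint simulator with recorded
ground truth underlies the test suite, so every stage is scored against
known parameters.

## The quantities the pipeline computes

**Exclusion-window RPKM.** For gene *g* with quantification segment length
*L<sub>g</sub>* (the full CDS, or the last exon for intron-containing
genes, with per-gene overrides such as using exon 2),

&nbsp;&nbsp;&nbsp;&nbsp;RPKM<sub>g</sub> = *n<sub>g</sub>* / (*L<sub>g</sub>*/10³) / (*N*<sub>nuc</sub>/10⁶)

where *n<sub>g</sub>* counts footprints whose assigned position (the
P-site, inferred from per-length calibrated offsets) lies in the segment
minus its first 10 and last 30 nt — initiating and terminating ribosomes
are excluded — and *N*<sub>nuc</sub> is the number of reads mapping to
nuclear protein-coding sequence. Normalizing the organellar signal to the
nuclear background keeps values comparable across samples even when
chloroplast translation itself changes.

**Ribosome density.** Ribo-seq RPKM / RNA-seq RPKM per gene — ribosomes
per mRNA. Condition comparisons report the per-replicate ratio mean ± SEM.

**Coverage tracks in RpM.** Per-position counts of footprint 3′ ends
(footprints translating the same codon share a 3′-end position regardless
of length), scaled to reads per million nuclear-CDS reads. These drive the
positional analyses below.

**Pause comparison.** Each position's fractional occupancy (share of its
ORF's reads) is compared between light and dark across independent
comparisons; positions under 30 RpM are discarded, and a site is flagged
only if it changes more than 2-fold in at least 2 comparisons.

**Run-off elongation analysis.** Lincomycin blocks peptide-bond formation
only for ribosomes with nascent chains shorter than ~5 amino acids, so
after treatment ORF bodies (codon 8 to the stop codon) drain at the
elongation rate. Percent-of-initial body RPKM over the time course, for
genes with t=0 RPKM > 100, gives per-gene clearance curves; the dark/light
ratio of percent remaining at 30 min > 1 indicates slower elongation in
the dark.

**Build-up-site caller.** Non-start positions whose 3′-end RpM rises ≥
5-fold by 30 min of lincomycin and reaches ≥ 50 RpM are called, annotated
with an ATG/GTG search (3′ end 9–18 nt downstream of the start codon), a
Shine-Dalgarno search (≥ 4 contiguous matches to AGGAGG, 4–14 nt upstream),
reading frame relative to the host ORF, and a coverage-matched control
position ≥ 500 nt away. Called positions are excluded from run-off body
counts, since captured initiation complexes would otherwise mask clearance.

## Worked example

The `demo` subcommand simulates a complete study — a 10-gene toy plastome
(one intron gene, psbA with a 6-fold light/dark ribosome-occupancy ratio),
three steady-state replicates per condition for Ribo-seq and RNA-seq, and
lincomycin time courses at 0/12/30 min in light and dark with the dark
elongation rate halved and three planted capture sites — then runs every
stage and scores recovery:

```bash
chlororibo demo --out demo_out --seed 7
```

prints (abridged):

```json
{
 "buildup_sites_called": 3,
 "buildup_sites_recovered": 3,
 "frame0_fraction": 0.8998852187221018,
 "genes_abs_log2_density_gt1": ["psbA"],
 "median_clearance_ratio_dark_vs_light": 1.4327170042425996,
 "median_replicate_pearson_r": 0.9996473237825605,
 "n_genes_in_runoff": 10,
 "n_pause_positions_flagged": 1,
 "planted_buildup_sites": 3,
 "psbA_ribo_light_dark_ratio": 6.029940187350708,
 "psbA_ribo_ratio_truth": 6.0
}
```

Reading this: the measured psbA footprint fold change (6.03) recovers the
planted 6-fold effect and psbA is the only gene whose ribosome density
shifts more than 2-fold; replicates correlate at r ≈ 0.9996; the frame-0
fraction matches the configured 0.9 frame fidelity; all 3 planted capture
sites are called with no false positives; the planted light-only pause
site is the single flagged position; and every gene clears ribosomes
faster in the light (median dark/light remaining ratio 1.43 at 30 min).
`demo_out/` holds the underlying tables (`quant.tsv`, `fold_changes.tsv`,
`pause_sites.tsv`, `buildup_sites.tsv`, `runoff_curves.tsv`,
`clearance_ratios.tsv`, `start_region_buildup.tsv`) plus a manifest; the
same seed always reproduces them byte for byte.

Other subcommands (`simulate`, `quantify`, `qc`, `compare`, `pauses`,
`runoff`, `buildup`) run each stage on files: a genome FASTA, a GFF3 or
flat-TSV annotation, per-sample alignment tables
(`<sample_id>.footprints.tsv`: chrom, start, end, sample, length, strand;
SAM/BAM also accepted by the library readers) and a sample sheet
(sample_id, assay, condition, timepoint_min, treatment, replicate).
Thresholds live in a YAML config mirroring `chlororibo.RunConfig`; every
run writes a `manifest.json` recording inputs, thresholds and seed.

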