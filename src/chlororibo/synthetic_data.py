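"""Toy plastome and footprint simulator with recorded ground truth.

The simulator emulates the statistical structure the analysis modules
assume: a small multi-ORF plastome over a nuclear-CDS read background,
18-40 nt footprints with 3-nt periodicity, a psbA-specific light/dark
occupancy ratio, lincomycin run-off time courses in which elongation
continues while newly initiating ribosomes freeze within the first few
codons, planted internal ribosome-capture sites preceded by Shine-Dalgarno
elements, and planted pause sites.

Geometry: footprints translating the same codon share the same 3'-end
position regardless of footprint length (the property the 3'-end track
analyses rest on).  A ribosome whose P-site starts at transcript position
``p`` yields a footprint whose 3' end sits ``three_prime_offset`` nt
downstream of ``p`` along the strand; the footprint length is drawn from a
categorical distribution and determines the 5' end.  Hence the 5'-to-P-site
offset of an ``L``-mer is ``L - three_prime_offset - 1`` (12 nt for the
default 28-mer), which the offset-calibration stage must recover.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (FOOTPRINT_COLUMNS, GeneModel, SampleMeta,
                         write_annotation_gff3, write_footprints,
                         write_sample_sheet)

CHLORO = "chloro"
NUCLEAR = "nuclear"

_COND_CODE = {"light": 1, "dark": 2}
_ASSAY_CODE = {"ribo": 1, "rna": 2}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted({a + b + c for a in "ACGT" for b in "ACGT"
                        for c in "ACGT"} - _STOPS)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationError(ValueError):
    """Invalid simulator configuration (e.g. a planted site colliding with
    an annotated start)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedBuildupSite:
    """An ectopic ribosome-capture site written into the toy plastome.

    ``position`` is the genomic coordinate of the first base of the
    start-like codon (strand orientation); leave ``None`` to auto-place the
    site mid-ORF.  ``sd_gap`` is the spacer (nt) between the last SD base
    and the start codon, drawn from the 5-13 nt range real plastid ribosome
    binding sites use.  ``capture_rate`` is expected captured footprints per
    minute of lincomycin exposure in the light; the dark rate is scaled
    down, mirroring slower initiation in the dark.
    """

    position: int | None = None
    strand: str = "+"
    sd_sequence: str = "AGGAGG"
    start_codon: str = "ATG"
    capture_rate: float = 12.0
    capture_rate_dark_factor: float = 0.25
    sd_gap: int = 8
    host_gene: str | None = None
    frame_shift: int = 0
    three_prime_pos: int | None = None   # filled in by build_toy_plastome


@dataclass
class PlantedPauseSite:
    gene_id: str
    codon: int
    multiplier: float = 3.0
    condition: str = "both"   # both | light | dark : where the extra dwell applies


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults give ~5e4 chloroplast footprints per sample over a ~10 kb
    10-gene plastome, a 6-fold psbA light/dark ribosome-occupancy ratio
    with condition-independent RNA, light elongation at 5 codons/min
    (halved in the dark), and a 1e6-read nuclear background so one read at
    a position corresponds to ~1 RpM.
    """

    n_genes: int = 10
    gene_length_range: tuple[int, int] = (600, 1200)
    spacer_length: int = 150
    intron_gene_index: int = 4
    intron_length: int = 150
    psbA_light_dark_ratio: float = 6.0
    global_occupancy: float = 6000.0      # dark-baseline footprints per kb CDS
    occupancy_spread: float = 2.0         # per-gene multiplier in [1/s, s]
    rna_abundance: float = 3000.0         # RNA-seq reads per kb CDS
    frame_fidelity: float = 0.9
    footprint_length_distribution: dict[int, float] = field(
        default_factory=lambda: {26: 0.1, 27: 0.2, 28: 0.4, 29: 0.2, 30: 0.1})
    initiation_length_distribution: dict[int, float] = field(
        default_factory=lambda: {22: 0.1, 23: 0.2, 24: 0.4, 25: 0.2, 26: 0.1})
    three_prime_offset: int = 15          # P-site first base -> 3' end, nt
    elongation_rate_light: float = 5.0    # codons/min
    elongation_rate_dark: float = 2.5
    lincomycin_block_codon: int = 7
    initiation_capture_rate_light: float = 2.0   # frozen reads/min/gene at starts
    initiation_capture_rate_dark: float = 0.5
    onset_delay_max: float = 0.0          # min; >0 spreads lincomycin onset
    planted_buildup_sites: list[PlantedBuildupSite] = field(default_factory=list)
    planted_pause_sites: list[PlantedPauseSite] = field(default_factory=list)
    nuclear_read_count: int = 1_000_000
    nuclear_cds_interval: tuple[int, int] = (1000, 31000)
    rna_read_length: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.frame_fidelity <= 1.0:
            raise SimulationError("frame_fidelity must be in [0, 1]")
        for name in ("global_occupancy", "rna_abundance"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        # elongation rate 0 is a valid degenerate condition (no run-off)
        for name in ("elongation_rate_light", "elongation_rate_dark"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3:
            raise SimulationError("gene lengths must be multiples of 3")
        for dist in (self.footprint_length_distribution,
                     self.initiation_length_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError("length distribution must sum to 1")
            if not all(18 <= k <= 40 for k in dist):
                raise SimulationError("footprint lengths must lie in 18-40 nt")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Realized parameters of one simulated sample (or time course)."""

    condition: str
    assay: str
    replicate: int
    nuclear_read_count: int
    gene_ids: list[str] = field(default_factory=list)
    occupancy_per_kb: dict[str, float] = field(default_factory=dict)
    occupancy_multiplier: dict[str, float] = field(default_factory=dict)
    expected_counts: dict[str, float] = field(default_factory=dict)
    realized_counts: dict[str, int] = field(default_factory=dict)
    expected_rpkm: dict[str, float] = field(default_factory=dict)
    # lincomycin time courses only:
    elongation_rate: float | None = None
    timepoints_min: list[float] = field(default_factory=list)
    expected_percent_remaining: dict[str, dict[str, float]] = field(
        default_factory=dict)
    buildup_sites: list[dict] = field(default_factory=list)
    pause_sites: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# plastome construction
# ---------------------------------------------------------------------------

@dataclass
class Plastome:
    sequences: dict[str, str]
    genes: list[GeneModel]                 # chloroplast genes + nuclear CDS
    buildup_sites: list[PlantedBuildupSite]
    occupancy_multiplier: dict[str, float]
    compartment_map: dict[str, str] = field(
        default_factory=lambda: {CHLORO: "chloroplast", NUCLEAR: "nuclear"})

    @property
    def chloro_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.seqid == CHLORO]

    @property
    def nuclear_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.seqid == NUCLEAR]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_body = length // 3 - 2
    body = rng.choice(_SENSE_CODONS, size=n_body)
    return "ATG" + "".join(body) + "TAA"


_CATEGORIES = ["photosynthesis", "ribosomal", "ndh", "other"]


def build_toy_plastome(config: SimConfig) -> Plastome:
    """Assemble the toy plastome, its annotation, and the nuclear contig.

    Genes are tiled alternately on both strands separated by UTR spacers;
    gene 0 is named ``psbA``; one gene carries an intron (so the last-exon
    quantification rule is exercised); planted build-up sites are written
    into the sequence as an ATG/GTG preceded by the designed SD element.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=config.n_genes) * 3
    spread = config.occupancy_spread
    log_mult = rng.uniform(-np.log(spread), np.log(spread),
                           size=config.n_genes)

    chunks: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    spacer = config.spacer_length
    mult: dict[str, float] = {}
    for i in range(config.n_genes):
        chunks.append("".join(rng.choice(list("ACGT"), size=spacer)))
        cursor += spacer
        gene_id = "psbA" if i == 0 else f"gene_{i:02d}"
        strand = "+" if i % 2 == 0 else "-"
        category = "photosynthesis" if i == 0 else _CATEGORIES[i % 4]
        cds = _random_cds(rng, int(lengths[i]))
        if i == config.intron_gene_index:
            ilen = config.intron_length
            # short first exon (~1/5 of the CDS, codon-boundary split) so
            # the quantified last exon sits within run-off reach
            len1 = max(3, (len(cds) // 15) * 3)
            len2 = len(cds) - len1
            intron = "".join(rng.choice(list("ACGT"), size=ilen))
            if strand == "+":
                segs = [(cursor, cursor + len1),
                        (cursor + len1 + ilen, cursor + len1 + ilen + len2)]
                chunks.append(cds[:len1] + intron + cds[len1:])
            else:
                glen = len(cds) + ilen
                segs = [(cursor + glen - len1, cursor + glen),
                        (cursor, cursor + len2)]
                chunks.append(revcomp(cds[len1:]) + intron + revcomp(cds[:len1]))
            cursor += len(cds) + ilen
            gm = GeneModel(gene_id, CHLORO, strand, segs, segs[-1], category)
        else:
            if strand == "+":
                segs = [(cursor, cursor + len(cds))]
                chunks.append(cds)
            else:
                segs = [(cursor, cursor + len(cds))]
                chunks.append(revcomp(cds))
            cursor += len(cds)
            gm = GeneModel(gene_id, CHLORO, strand, segs, segs[0], category)
        genes.append(gm)
        mult[gene_id] = float(np.exp(log_mult[i]))
    chunks.append("".join(rng.choice(list("ACGT"), size=spacer)))
    cursor += spacer

    seq = list("".join(chunks))
    sites = _resolve_buildup_sites(config, genes, seq, rng)

    a, b = config.nuclear_cds_interval
    nuc_len = b + 1000
    nuc_seq = "".join(rng.choice(list("ACGT"), size=nuc_len))
    nuc_gene = GeneModel("nuclear_cds", NUCLEAR, "+", [(a, b)], (a, b),
                         "other")
    return Plastome({CHLORO: "".join(seq), NUCLEAR: nuc_seq},
                    genes + [nuc_gene], sites, mult)


def _start_region_positions(genes, start_codons=7):
    """Genomic positions covered by the first ``start_codons`` codons,
    keyed by strand."""
    regions: dict[str, set[int]] = {"+": set(), "-": set()}
    for g in genes:
        tpos = np.arange(min(3 * start_codons, g.cds_length))
        regions[g.strand].update(int(p) for p in g.transcript_to_genomic(tpos))
    return regions


def _resolve_buildup_sites(config, genes, seq, rng):
    start_regions = _start_region_positions(genes,
                                            config.lincomycin_block_codon)
    # auto-placement avoids the intron gene (junction geometry) and psbA
    # (whose light-specific occupancy would confound the planted effect)
    eligible = [g for g in genes
                if not g.has_intron and g.gene_id != "psbA"]
    sites = []
    for i, proto in enumerate(config.planted_buildup_sites):
        site = dataclasses.replace(proto)
        if site.position is None:
            host = (next(g for g in eligible if g.gene_id == site.host_gene)
                    if site.host_gene else eligible[i % len(eligible)])
            n_codons = host.cds_length // 3
            # sites sharing a host sit >= 12 codons apart so one site's SD
            # element can never overwrite another's start codon
            codon = n_codons // 3 + 12 * (i // len(eligible)) + 3 * (i % 4)
            tpos = 3 * codon + (site.frame_shift % 3)
            site.position = int(host.transcript_to_genomic(tpos))
            site.strand = host.strand
            site.host_gene = host.gene_id
        if site.position in start_regions[site.strand]:
            raise SimulationError(
                f"planted build-up site at {site.position} ({site.strand}) "
                "collides with an annotated start-codon region")
        _write_site(seq, site)
        d3 = config.three_prime_offset
        site.three_prime_pos = (site.position + d3 if site.strand == "+"
                                else site.position - d3)
        sites.append(site)
    return sites


def _write_site(seq, site):
    """Write start codon + SD element into the sequence, strand-aware."""
    pos, gap, sd, codon = (site.position, site.sd_gap, site.sd_sequence,
                           site.start_codon)
    if not 5 <= gap <= 13:
        raise SimulationError("sd_gap must lie in 5-13 nt")
    if codon not in ("ATG", "GTG"):
        raise SimulationError("start codon must be ATG or GTG")
    if site.strand == "+":
        seq[pos:pos + 3] = list(codon)
        seq[pos - gap - len(sd):pos - gap] = list(sd)
    else:
        seq[pos - 2:pos + 1] = list(revcomp(codon))
        seq[pos + gap + 1:pos + gap + 1 + len(sd)] = list(revcomp(sd))


# ---------------------------------------------------------------------------
# read emission helpers
# ---------------------------------------------------------------------------

def _sample_rng(config, condition, assay, replicate, salt):
    return np.random.default_rng([config.seed, _COND_CODE[condition],
                                  _ASSAY_CODE[assay], replicate, salt])


def _length_arrays(dist):
    lengths = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[int(k)] for k in lengths])
    return lengths, probs / probs.sum()


def _emit_footprints(gene, psites_t, lengths, d3, sample_id):
    """Turn P-site transcript positions into footprint rows.

    The 3' end is at a fixed strand-aware offset from the P-site; the 5'
    end follows from the drawn length.  Footprints are emitted as unspliced
    genomic intervals anchored at their 3' end (assigned-position analyses
    only ever use one end).
    """
    gpos = gene.transcript_to_genomic(psites_t)
    if gene.strand == "+":
        end = gpos + d3 + 1
        start = end - lengths
    else:
        start = gpos - d3
        end = start + lengths
    return pd.DataFrame({"seqid": gene.seqid, "start": start, "end": end,
                         "sample_id": sample_id, "length": lengths,
                         "strand": gene.strand})


def _jitter(psites, fidelity, rng, cds_len):
    u = rng.random(psites.size)
    off = np.where(u < (1 - fidelity) / 2, -1,
                   np.where(u < (1 - fidelity), 1, 0))
    return np.clip(psites + off, 0, cds_len - 1)


def _nuclear_reads(config, rng, sample_id, assay):
    a, b = config.nuclear_cds_interval
    n = config.nuclear_read_count
    if assay == "ribo":
        lengths, probs = _length_arrays(config.footprint_length_distribution)
        L = rng.choice(lengths, size=n, p=probs)
    else:
        L = np.full(n, config.rna_read_length, dtype=np.int64)
    start = rng.integers(a, b - int(L.max()), size=n)
    return pd.DataFrame({"seqid": NUCLEAR, "start": start, "end": start + L,
                         "sample_id": sample_id, "length": L,
                         "strand": "+"})


def _finalize(frames):
    df = pd.concat(frames, ignore_index=True)[FOOTPRINT_COLUMNS]
    for col in ("seqid", "sample_id", "strand"):
        df[col] = df[col].astype("category")   # memory: mostly-repeated strings
    return df


# ---------------------------------------------------------------------------
# steady-state simulation
# ---------------------------------------------------------------------------

def _gene_occupancy(config, plastome, gene, condition):
    occ = config.global_occupancy * plastome.occupancy_multiplier[gene.gene_id]
    if gene.gene_id == "psbA" and condition == "light":
        occ *= config.psbA_light_dark_ratio
    return occ


def _codon_lambda(config, gene, occ_per_kb, condition):
    n_codons = gene.cds_length // 3
    lam = np.full(n_codons, 3.0 * occ_per_kb / 1000.0)
    for ps in config.planted_pause_sites:
        if ps.gene_id == gene.gene_id and ps.condition in ("both", condition):
            lam[ps.codon] *= ps.multiplier
    return lam


def simulate_steady_state(config: SimConfig, plastome: Plastome,
                          condition: str, assay: str, replicate: int
                          ) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one steady-state sample (no lincomycin).

    Ribo-seq: per-codon footprint counts are Poisson around
    occupancy x length, with only psbA's occupancy scaled by the light/dark
    ratio.  RNA-seq: reads uniform over the spliced CDS, condition
    independent.  A nuclear background of exactly
    ``config.nuclear_read_count`` reads is appended.
    """
    config.validate()
    sample_id = f"{assay}_{condition}_r{replicate}"
    rng = _sample_rng(config, condition, assay, replicate, 7)
    truth = SimTruth(condition, assay, replicate, config.nuclear_read_count)
    frames = []
    lengths_e, probs_e = _length_arrays(config.footprint_length_distribution)
    d3 = config.three_prime_offset
    for gene in plastome.chloro_genes:
        truth.gene_ids.append(gene.gene_id)
        truth.occupancy_multiplier[gene.gene_id] = \
            plastome.occupancy_multiplier[gene.gene_id]
        if assay == "ribo":
            occ = _gene_occupancy(config, plastome, gene, condition)
            lam = _codon_lambda(config, gene, occ, condition)
            counts = rng.poisson(lam)
            codons = np.repeat(np.arange(lam.size), counts)
            psites = _jitter(3 * codons, config.frame_fidelity, rng,
                             gene.cds_length)
            L = rng.choice(lengths_e, size=psites.size, p=probs_e)
            frames.append(_emit_footprints(gene, psites, L, d3, sample_id))
            truth.occupancy_per_kb[gene.gene_id] = occ
            truth.expected_counts[gene.gene_id] = float(lam.sum())
            truth.realized_counts[gene.gene_id] = int(counts.sum())
            truth.expected_rpkm[gene.gene_id] = _expected_rpkm(
                config, gene, occ)
        else:
            n = rng.poisson(config.rna_abundance * gene.cds_length / 1000.0)
            mids_t = rng.integers(0, gene.cds_length, size=n)
            gmid = gene.transcript_to_genomic(mids_t)
            L = config.rna_read_length
            start = gmid - L // 2
            frames.append(pd.DataFrame(
                {"seqid": gene.seqid, "start": start, "end": start + L,
                 "sample_id": sample_id, "length": L,
                 "strand": gene.strand}))
            truth.occupancy_per_kb[gene.gene_id] = config.rna_abundance
            truth.expected_counts[gene.gene_id] = \
                config.rna_abundance * gene.cds_length / 1000.0
            truth.realized_counts[gene.gene_id] = int(n)
            truth.expected_rpkm[gene.gene_id] = (
                config.rna_abundance * (gene.cds_length / 1000.0)
                / (gene.cds_length / 1000.0)
                / (config.nuclear_read_count / 1e6))
    frames.append(_nuclear_reads(config, rng, sample_id, assay))
    return _finalize(frames), truth


def _expected_rpkm(config, gene, occ_per_kb, exclude=(10, 30)):
    """Expected Ribo-seq RPKM under the exclusion-window counting rule."""
    lo, hi = gene.quant_transcript_window()
    lo, hi = lo + exclude[0], hi - exclude[1]
    eligible_nt = max(0, hi - lo)
    expected = occ_per_kb / 1000.0 * eligible_nt
    return expected / (gene.quant_length / 1000.0) / \
        (config.nuclear_read_count / 1e6)


# ---------------------------------------------------------------------------
# lincomycin time courses
# ---------------------------------------------------------------------------

def _survival(config, n_codons, rate, t):
    """P(a body codon is still occupied at time t) per codon index.

    Deterministic run-off front: ribosomes within rate*t codons of the
    block are not replaced.  A uniform per-chloroplast onset delay (off by
    default) smooths the front.
    """
    block = config.lincomycin_block_codon
    c = np.arange(n_codons, dtype=float)
    surv = np.zeros(n_codons)
    body = c >= block
    if rate <= 0:
        surv[body] = 1.0
        return surv
    cleared_by = t - (c - block) / rate      # onset delay needed to survive
    if config.onset_delay_max > 0:
        surv[body] = np.clip(cleared_by[body] / config.onset_delay_max,
                             0.0, 1.0)
        surv[body] = 1.0 - surv[body]
    else:
        surv[body] = (cleared_by[body] <= 0).astype(float)
    return surv


def simulate_lincomycin_timecourse(config: SimConfig, plastome: Plastome,
                                   condition: str,
                                   timepoints_min: Sequence[float],
                                   replicate: int
                                   ) -> tuple[dict[float, pd.DataFrame],
                                              SimTruth]:
    """Simulate ribosome run-off after lincomycin at t=0.

    Loaded ribosomes beyond the block codon advance at the condition's
    elongation rate and leave at the stop codon; ribosomes in the first
    ``lincomycin_block_codon`` codons freeze; new initiators accumulate
    frozen in the start region; planted capture sites accumulate
    initiation-mode footprints at their capture rate.
    """
    config.validate()
    if any(t < 0 for t in timepoints_min):
        raise SimulationError("timepoints must be non-negative")
    if 0 not in [float(t) for t in timepoints_min]:
        raise SimulationError("timepoints must include 0")
    rate = (config.elongation_rate_light if condition == "light"
            else config.elongation_rate_dark)
    init_rate = (config.initiation_capture_rate_light if condition == "light"
                 else config.initiation_capture_rate_dark)
    block = config.lincomycin_block_codon
    d3 = config.three_prime_offset
    lengths_e, probs_e = _length_arrays(config.footprint_length_distribution)
    lengths_i, probs_i = _length_arrays(config.initiation_length_distribution)

    truth = SimTruth(condition, "ribo", replicate, config.nuclear_read_count,
                     elongation_rate=rate,
                     timepoints_min=[float(t) for t in timepoints_min])
    out: dict[float, pd.DataFrame] = {}
    rng = _sample_rng(config, condition, "ribo", replicate, 13)
    for t in timepoints_min:
        t = float(t)
        sample_id = f"lin_{condition}_t{t:g}_r{replicate}"
        frames = []
        for gene in plastome.chloro_genes:
            occ = _gene_occupancy(config, plastome, gene, condition)
            lam0 = _codon_lambda(config, gene, occ, condition)
            n_codons = lam0.size
            surv = _survival(config, n_codons, rate, t)
            lam_body = lam0 * surv
            lam_start = lam0.copy()
            lam_start[block:] = 0.0
            if t > 0:
                lam_start[:block] += init_rate * t / block
            # body footprints: elongating length distribution
            cb = rng.poisson(lam_body)
            codons_b = np.repeat(np.arange(n_codons), cb)
            ps_b = _jitter(3 * codons_b, config.frame_fidelity, rng,
                           gene.cds_length)
            Lb = rng.choice(lengths_e, size=ps_b.size, p=probs_e)
            frames.append(_emit_footprints(gene, ps_b, Lb, d3, sample_id))
            # start-region footprints: initiation-mode lengths once frozen
            cs = rng.poisson(lam_start)
            codons_s = np.repeat(np.arange(n_codons), cs)
            ps_s = _jitter(3 * codons_s, config.frame_fidelity, rng,
                           gene.cds_length)
            Ls = rng.choice(lengths_i if t > 0 else lengths_e,
                            size=ps_s.size,
                            p=probs_i if t > 0 else probs_e)
            frames.append(_emit_footprints(gene, ps_s, Ls, d3, sample_id))
            # truth covers the same region the run-off analysis measures:
            # the quantification segment minus the first `block` ORF codons
            qlo, qhi = gene.quant_transcript_window()
            body = slice(max(block, qlo // 3), qhi // 3)
            if t == 0:
                truth.gene_ids.append(gene.gene_id)
                truth.occupancy_per_kb[gene.gene_id] = occ
                truth.expected_counts[gene.gene_id] = float(
                    lam0[body].sum())
                truth.expected_rpkm[gene.gene_id] = _expected_rpkm(
                    config, gene, occ,
                    exclude=(max(0, 3 * block - qlo), 0))
            pct = 100.0 * lam0[body].dot(surv[body]) / lam0[body].sum()
            truth.expected_percent_remaining.setdefault(
                gene.gene_id, {})[f"{t:g}"] = float(pct)
        # planted capture sites: frozen initiation complexes, exact 3' ends
        for site in plastome.buildup_sites:
            rate_site = site.capture_rate * (
                1.0 if condition == "light" else site.capture_rate_dark_factor)
            n_cap = rng.poisson(rate_site * t)
            if n_cap:
                L = rng.choice(lengths_i, size=n_cap, p=probs_i)
                tp = site.three_prime_pos
                if site.strand == "+":
                    start = tp + 1 - L
                    end = np.full(n_cap, tp + 1)
                else:
                    start = np.full(n_cap, tp)
                    end = start + L
                frames.append(pd.DataFrame(
                    {"seqid": CHLORO, "start": start, "end": end,
                     "sample_id": sample_id, "length": L,
                     "strand": site.strand}))
            if t == max(float(x) for x in timepoints_min):
                truth.buildup_sites.append({
                    "position": site.position, "strand": site.strand,
                    "three_prime_pos": site.three_prime_pos,
                    "host_gene": site.host_gene,
                    "sd_sequence": site.sd_sequence,
                    "start_codon": site.start_codon,
                    "expected_t_final_rpm": rate_site * t * 1e6
                    / config.nuclear_read_count,
                    "realized_captured": int(n_cap)})
        frames.append(_nuclear_reads(config, rng, sample_id, "ribo"))
        out[t] = _finalize(frames)
    return out, truth


# ---------------------------------------------------------------------------
# study-level convenience wrappers
# ---------------------------------------------------------------------------

def simulate_light_shift_study(config: SimConfig, plastome: Plastome,
                               n_replicates: int = 3):
    """Light vs dark steady state, ribo + rna, ``n_replicates`` each.

    Returns ``(samples, truths)`` keyed by sample id; samples are
    ``(SampleMeta, DataFrame)``.
    """
    samples, truths = {}, {}
    for condition in ("light", "dark"):
        for assay in ("ribo", "rna"):
            for rep in range(1, n_replicates + 1):
                df, truth = simulate_steady_state(config, plastome,
                                                  condition, assay, rep)
                sid = f"{assay}_{condition}_r{rep}"
                samples[sid] = (SampleMeta(sid, assay, condition,
                                           replicate=rep), df)
                truths[sid] = truth
    return samples, truths


def simulate_lincomycin_study(config: SimConfig, plastome: Plastome,
                              timepoints_min: Sequence[float] = (0, 12, 30),
                              n_replicates: int = 2,
                              conditions: Sequence[str] = ("light", "dark")):
    """Lincomycin run-off time courses for both conditions."""
    samples, truths = {}, {}
    for condition in conditions:
        for rep in range(1, n_replicates + 1):
            per_t, truth = simulate_lincomycin_timecourse(
                config, plastome, condition, timepoints_min, rep)
            truths[f"lin_{condition}_r{rep}"] = truth
            for t, df in per_t.items():
                sid = f"lin_{condition}_t{t:g}_r{rep}"
                samples[sid] = (SampleMeta(sid, "ribo", condition,
                                           timepoint_min=t,
                                           treatment="lincomycin",
                                           replicate=rep), df)
    return samples, truths


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(plastome: Plastome, samples: Mapping, truths: Mapping,
                     out_dir) -> dict:
    """Emit FASTA, GFF3, per-sample footprint TSVs, sample sheet and truth
    JSON for a simulated study."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    fasta = os.path.join(out_dir, "genome.fasta")
    SeqIO.write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in plastome.sequences.items()], fasta, "fasta")
    paths["genome"] = fasta
    gff = os.path.join(out_dir, "annotation.gff3")
    write_annotation_gff3(plastome.genes, gff)
    paths["annotation"] = gff
    metas = []
    for sid, (meta, df) in samples.items():
        p = os.path.join(out_dir, f"{sid}.footprints.tsv")
        write_footprints(df, p)
        paths[sid] = p
        metas.append(meta)
    sheet = os.path.join(out_dir, "samples.tsv")
    write_sample_sheet(metas, sheet)
    paths["sample_sheet"] = sheet
    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in truths.items()}, fh,
                  indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths
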