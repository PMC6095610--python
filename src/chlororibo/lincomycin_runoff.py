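"""Ribosome run-off (elongation-rate) analysis and the ectopic ribosome
build-up-site caller.

Lincomycin blocks peptide-bond formation only for ribosomes with very
short nascent chains, so after treatment the ORF body (codon 8 to the stop
codon) drains at the elongation rate while ribosomes pile up at start
codons and at ectopic start-like sites.  The caller finds non-start
positions on the 3'-end track whose normalized coverage rises at least
``min_fold`` by the final timepoint and reaches ``min_rpm``, annotates
each with a start-codon and Shine-Dalgarno search plus reading frame, and
pairs it with a coverage-matched control position.  Build-up positions are
excluded from the body counts that the percent-remaining run-off curves
are computed from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel
from .quantify import count_gene, pool_tracks, rpkm

logger = logging.getLogger("chlororibo")

SD_CONSENSUS = "AGGAGG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sd_substrings(min_match: int):
    subs = set()
    for i in range(len(SD_CONSENSUS)):
        for j in range(i + min_match, len(SD_CONSENSUS) + 1):
            subs.add(SD_CONSENSUS[i:j])
    return sorted(subs, key=len, reverse=True)


# ---------------------------------------------------------------------------
# sequence annotation of a site
# ---------------------------------------------------------------------------

def annotate_sd(genome: str, three_prime_pos: int, strand: str,
                start_window: tuple[int, int] = (9, 18),
                sd_gap: tuple[int, int] = (4, 14),
                sd_min_match: int = 4) -> dict:
    """Start-codon and Shine-Dalgarno search around a footprint 3' end.

    A start-like codon (ATG/GTG) is sought such that the 3' end lies
    ``start_window`` nt downstream of its first base (strand orientation);
    an SD element is any run of >= ``sd_min_match`` contiguous bases
    matching the AGGAGG consensus whose last base sits ``sd_gap`` nt
    upstream of the start codon.  Among candidate start codons, one with
    an SD match is preferred; ties break toward the middle of the window.
    Sites too close to the sequence edge return a partial annotation with
    ``edge_truncated`` set.
    """
    wlo, whi = start_window
    glo, ghi = sd_gap
    # oriented coordinate: k nt upstream of the 3' end along the strand
    span = whi + ghi + len(SD_CONSENSUS)
    if strand == "+":
        lo = three_prime_pos - span
        hi = three_prime_pos + 1
        oriented = genome[max(lo, 0):hi]
        truncated = lo < 0
    else:
        lo = three_prime_pos
        hi = three_prime_pos + span + 1
        oriented = _revcomp(genome[lo:min(hi, len(genome))])
        truncated = hi > len(genome)
    # oriented[-1] is the 3'-end base; index from the right
    result = {"start_codon_found": "none", "start_codon_offset": None,
              "sd_match": False, "sd_substring": "",
              "edge_truncated": truncated}
    mid = (wlo + whi) / 2.0
    candidates = []
    for w in range(wlo, whi + 1):
        # first base of candidate codon is w nt upstream of the 3' end
        i = len(oriented) - 1 - w
        if i < 0 or i + 3 > len(oriented):
            continue
        codon = oriented[i:i + 3]
        if codon not in ("ATG", "GTG"):
            continue
        sd_sub = ""
        window = oriented[max(0, i - ghi - len(SD_CONSENSUS)):max(0, i - glo)]
        for sub in _sd_substrings(sd_min_match):
            if sub in window:
                sd_sub = sub
                break
        # prefer the candidate with the strongest SD complementarity,
        # then the one closest to the expected spacing
        candidates.append((-len(sd_sub), abs(w - mid), w, codon, sd_sub))
    if candidates:
        _, _, w, codon, sd_sub = min(candidates)
        result.update(start_codon_found=codon, start_codon_offset=w,
                      sd_match=bool(sd_sub), sd_substring=sd_sub)
    return result


# ---------------------------------------------------------------------------
# build-up site detection
# ---------------------------------------------------------------------------

@dataclass
class BuildupThresholds:
    min_rpm: float = 50.0
    min_fold: float = 5.0
    start_region_codons: int = 7
    three_prime_offset: int = 15


def _host_gene(genes, pos, strand, seqid):
    for g in genes:
        if g.seqid == seqid and g.strand == strand and \
                int(g.genomic_to_transcript(pos)) >= 0:
            return g
    return None


def detect_buildup_sites(tracks_t0: Sequence[CoverageTrack],
                         tracks_t_final: Sequence[CoverageTrack],
                         genes: Sequence[GeneModel],
                         genome: str,
                         thresholds: BuildupThresholds | None = None,
                         start_window: tuple[int, int] = (9, 18),
                         sd_gap: tuple[int, int] = (4, 14),
                         sd_min_match: int = 4) -> pd.DataFrame:
    """Call positions where 3'-end coverage builds up during lincomycin.

    A position qualifies when its replicate-mean RpM at the final
    timepoint reaches ``min_rpm``, its fold increase over t=0 reaches
    ``min_fold`` (a zero t=0 gives an infinite-fold flag and still
    qualifies), and its implied P-site (3' end minus the fixed 3' offset)
    does not fall within the first ``start_region_codons`` codons of an
    annotated gene on the same strand.  Tracks must be light-condition
    3'-end tracks sharing the nuclear-CDS normalization.
    """
    if not tracks_t0:
        raise ValueError("detect_buildup_sites: t=0 tracks are required")
    th = thresholds or BuildupThresholds()
    d3 = th.three_prime_offset
    start_psites = {"+": set(), "-": set()}
    for g in genes:
        tpos = np.arange(min(3 * th.start_region_codons, g.cds_length))
        start_psites[g.strand].update(
            int(p) for p in g.transcript_to_genomic(tpos))
    seqid = tracks_t0[0].seqid
    rows = []
    for strand in "+-":
        rpm0 = np.mean([t.rpm(strand) for t in tracks_t0], axis=0)
        rpmf = np.mean([t.rpm(strand) for t in tracks_t_final], axis=0)
        for pos in np.flatnonzero(rpmf >= th.min_rpm):
            pos = int(pos)
            infinite = rpm0[pos] == 0
            fold = np.inf if infinite else rpmf[pos] / rpm0[pos]
            if fold < th.min_fold:
                continue
            psite = pos - d3 if strand == "+" else pos + d3
            if psite in start_psites[strand]:
                continue
            host = _host_gene(genes, psite, strand, seqid)
            ann = annotate_sd(genome, pos, strand, start_window, sd_gap,
                              sd_min_match)
            in_frame = None
            if host is not None:
                in_frame = int(host.genomic_to_transcript(psite)) % 3 == 0
            rows.append({
                "position_1based": pos + 1, "strand": strand,
                "rpm_t0": float(rpm0[pos]), "rpm_t_final": float(rpmf[pos]),
                "fold_increase": float(fold), "infinite_fold": infinite,
                "is_annotated_start": False,
                "host_gene": host.gene_id if host else "UTR",
                "in_frame_with_host": in_frame,
                **ann})
    df = pd.DataFrame(rows, columns=[
        "position_1based", "strand", "rpm_t0", "rpm_t_final",
        "fold_increase", "infinite_fold", "is_annotated_start", "host_gene",
        "in_frame_with_host", "start_codon_found", "start_codon_offset",
        "sd_match", "sd_substring", "edge_truncated"])
    return df.sort_values(["strand", "position_1based"],
                          ignore_index=True) if len(df) else df


def buildup_positions(sites: pd.DataFrame) -> dict[str, set[int]]:
    """Genomic 0-based 3'-end positions of called sites, per strand."""
    out = {"+": set(), "-": set()}
    for r in sites.itertuples():
        out[r.strand].add(int(r.position_1based) - 1)
    return out


# ---------------------------------------------------------------------------
# matched control sites
# ---------------------------------------------------------------------------

def match_control_sites(sites: pd.DataFrame,
                        tracks_t0: Sequence[CoverageTrack],
                        min_distance: int = 500,
                        band_factor: float = 2.0,
                        widen_step: float = 1.5) -> pd.DataFrame:
    """Pair each site with the nearest same-strand position, at least
    ``min_distance`` nt away, with a similar t=0 read level.

    "Similar" means t=0 RpM within ``band_factor``-fold; when no candidate
    exists the band widens geometrically by ``widen_step`` until one does
    (the final band is recorded per site).  Sites with zero t=0 coverage
    have no ratio-comparable control and get none.
    """
    out = sites.copy()
    controls, bands, control_rpm = [], [], []
    for r in sites.itertuples():
        rpm0 = np.mean([t.rpm(r.strand) for t in tracks_t0], axis=0)
        pos = int(r.position_1based) - 1
        target = rpm0[pos]
        if target == 0:
            controls.append(np.nan)
            bands.append(np.nan)
            control_rpm.append(np.nan)
            continue
        cand = np.flatnonzero(rpm0 > 0)
        cand = cand[np.abs(cand - pos) >= min_distance]
        band = band_factor
        chosen = None
        while chosen is None and band < 1e6:
            in_band = cand[(rpm0[cand] >= target / band) &
                           (rpm0[cand] <= target * band)]
            if in_band.size:
                chosen = int(in_band[np.argmin(np.abs(in_band - pos))])
            else:
                band *= widen_step
        if chosen is None:
            controls.append(np.nan)
            bands.append(np.nan)
            control_rpm.append(np.nan)
            continue
        if band > band_factor:
            logger.info("match_control_sites: site %d (%s) needed band "
                        "x%.2f", pos + 1, r.strand, band)
        controls.append(chosen + 1)
        bands.append(band)
        control_rpm.append(float(rpm0[chosen]))
    out["control_position_1based"] = controls
    out["control_band_factor"] = bands
    out["control_rpm_t0"] = control_rpm
    return out


# ---------------------------------------------------------------------------
# run-off curves
# ---------------------------------------------------------------------------

def runoff_curves(samples: Mapping[tuple[str, float, int],
                                   tuple[pd.DataFrame, int]],
                  genes: Sequence[GeneModel],
                  excluded_positions: Mapping[str, set[int]] | None = None,
                  min_t0_rpkm: float = 100.0,
                  block_codons: int = 7,
                  position_semantics: str = "p_site_from_three_prime",
                  offsets=None,
                  three_prime_offset: int = 15) -> pd.DataFrame:
    """Percent-of-initial body RPKM per gene over the lincomycin course.

    ``samples`` maps ``(condition, timepoint_min, replicate)`` to
    ``(footprint frame, nuclear_cds_reads)``.  Body counts cover codon
    ``block_codons``+1 to the stop codon of the quantification segment
    (the first codons hold lincomycin-frozen ribosomes); the default
    semantics assigns each read the P-site implied by its 3' end, and the
    3'-end positions of called build-up sites are additionally excluded.
    Genes whose replicate-mean body RPKM at t=0 is not above
    ``min_t0_rpkm`` are reported with ``included=False``; t=0 RPKM of
    zero excludes a gene outright.
    """
    excluded_positions = excluded_positions or {}
    keys = sorted(samples)
    conditions = sorted({k[0] for k in keys})
    timepoints = sorted({k[1] for k in keys})
    if 0 not in timepoints:
        raise ValueError("runoff_curves: timepoints must include 0")
    rows = []
    for cond in conditions:
        reps = sorted({k[2] for k in keys if k[0] == cond})
        for gene in genes:
            # exclude the first `block_codons` codons of the ORF; for an
            # intron gene quantified from its last exon the segment may
            # already start past them
            qlo, _ = gene.quant_transcript_window()
            exclude = (max(0, 3 * block_codons - qlo), 0)
            # build-up sites are 3'-end positions; shift them onto the
            # implied-P-site coordinate the body count is taken in
            excl = excluded_positions.get(gene.strand, set())
            if position_semantics == "p_site_from_three_prime" and excl:
                shift = (-three_prime_offset if gene.strand == "+"
                         else three_prime_offset)
                excl = {p + shift for p in excl}
            body_rpkm = {}
            for t in timepoints:
                per_rep = []
                for rep in reps:
                    df, nuc = samples[(cond, t, rep)]
                    n = count_gene(df, gene, "ribo", position_semantics,
                                   offsets, exclude,
                                   excluded_positions=excl,
                                   three_prime_offset=three_prime_offset)
                    per_rep.append(rpkm(n, gene, nuc) if n is not None
                                   else np.nan)
                body_rpkm[t] = float(np.nanmean(per_rep))
            t0 = body_rpkm[0]
            if t0 == 0 or np.isnan(t0):
                logger.info("runoff_curves: %s (%s) excluded, t0 RPKM = %s",
                            gene.gene_id, cond, t0)
                continue
            included = t0 > min_t0_rpkm
            for t in timepoints:
                rows.append({"gene_id": gene.gene_id, "condition": cond,
                             "timepoint_min": t,
                             "body_rpkm": body_rpkm[t],
                             "percent_of_t0": 100.0 * body_rpkm[t] / t0,
                             "t0_body_rpkm": t0,
                             "included": included})
    return pd.DataFrame(rows)


def clearance_ratio(curves: pd.DataFrame, t: float = 30.0,
                    conditions: tuple[str, str] = ("dark", "light")
                    ) -> pd.DataFrame:
    """Per-gene ratio of percent-remaining at time ``t`` between
    conditions (default dark/light; > 1 means slower elongation in the
    dark).  Genes missing in either condition, or not passing the t=0
    filter in both, are omitted."""
    num_c, den_c = conditions
    inc = curves[curves["included"] & (curves["timepoint_min"] == t)]
    num = inc[inc["condition"] == num_c].set_index("gene_id")[
        "percent_of_t0"]
    den = inc[inc["condition"] == den_c].set_index("gene_id")[
        "percent_of_t0"]
    shared = sorted(set(num.index) & set(den.index))
    skipped = sorted(set(num.index) ^ set(den.index))
    if skipped:
        logger.info("clearance_ratio: omitted %s (missing in one "
                    "condition)", skipped)
    rows = [{"gene_id": g,
             "percent_remaining_" + num_c: float(num[g]),
             "percent_remaining_" + den_c: float(den[g]),
             "ratio": float(num[g] / den[g]) if den[g] else np.inf}
            for g in shared]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# start-region build-up
# ---------------------------------------------------------------------------

def start_region_buildup(tracks: Mapping[float, CoverageTrack],
                         genes: Sequence[GeneModel],
                         start_codons: int = 7,
                         three_prime_offset: int = 15) -> pd.DataFrame:
    """Per-gene start-region RpM over the time course, with a trend slope.

    The start region is the first ``start_codons`` codons; on a 3'-end
    track the corresponding assigned positions are shifted by the fixed
    3' offset.  A metagene row averages the per-gene series.  Slopes are
    least-squares RpM-per-minute; under lincomycin they are positive
    (initiating ribosomes freeze in place), and larger in the light.
    """
    times = sorted(tracks)
    shift = three_prime_offset if \
        next(iter(tracks.values())).position_semantics == \
        "three_prime_end" else 0
    rows = []
    series_matrix = []
    for g in genes:
        tpos = np.arange(shift, min(3 * start_codons + shift, g.cds_length))
        gpos = g.transcript_to_genomic(tpos)
        series = []
        for t in times:
            tr = tracks[t]
            series.append(float(tr.rpm(g.strand)[gpos].sum()))
        slope = float(np.polyfit(times, series, 1)[0]) if len(times) > 1 \
            else 0.0
        row = {"gene_id": g.gene_id, "slope_rpm_per_min": slope,
               "slope_sign": int(np.sign(slope))}
        row.update({f"rpm_t{t:g}": v for t, v in zip(times, series)})
        rows.append(row)
        series_matrix.append(series)
    mean_series = np.mean(series_matrix, axis=0)
    meta = {"gene_id": "metagene",
            "slope_rpm_per_min": float(np.polyfit(times, mean_series, 1)[0])
            if len(times) > 1 else 0.0}
    meta["slope_sign"] = int(np.sign(meta["slope_rpm_per_min"]))
    meta.update({f"rpm_t{t:g}": float(v)
                 for t, v in zip(times, mean_series)})
    rows.append(meta)
    return pd.DataFrame(rows)
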