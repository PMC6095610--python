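"""Condition comparisons: light/dark fold changes of footprint abundance,
mRNA abundance and ribosome density, plus the positional pause-site
comparison.

Fold changes are computed per replicate pair and summarized as mean ± SEM
across replicates.  Ribosome density is Ribo-seq/RNA-seq, so
its per-replicate ratio is the ribo ratio divided by the rna ratio.  The
pause comparison works on fractional occupancy (each position's share of
its ORF's reads), discards positions below an RpM floor, and flags a
position only when it changes more than ``min_fold`` in at least
``min_comparisons`` independent light/dark comparisons.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel

logger = logging.getLogger("chlororibo")


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def _replicate_ratios(quant, gene_id, assay, cond_a, cond_b):
    sub = quant[(quant["gene_id"] == gene_id) & (quant["assay"] == assay) &
                (quant["treatment"] == "none")]
    a = sub[sub["condition"] == cond_a].set_index("replicate")["rpkm"]
    b = sub[sub["condition"] == cond_b].set_index("replicate")["rpkm"]
    ratios, dropped = [], []
    for rep in sorted(set(a.index) & set(b.index)):
        if b[rep] == 0 or np.isnan(a[rep]) or np.isnan(b[rep]):
            dropped.append(rep)
            continue
        ratios.append(a[rep] / b[rep])
    if dropped:
        logger.info("fold_changes: %s/%s dropped replicates %s "
                    "(zero or undefined denominator)", gene_id, assay,
                    dropped)
    return ratios


def fold_changes(quant: pd.DataFrame,
                 contrast: tuple[str, str] = ("light", "dark"),
                 min_orf_len: int = 150) -> pd.DataFrame:
    """Per-gene mean ± SEM of light/dark RPKM ratios for ribo, rna and
    density.

    Genes whose mRNA level cannot be measured with confidence — short ORFs
    (< ``min_orf_len``) and intron-containing genes — are excluded from
    the rna and density ratios (the ribo ratio is still reported).
    """
    cond_a, cond_b = contrast
    rows = []
    for gene_id in quant["gene_id"].unique():
        flags = quant[quant["gene_id"] == gene_id].iloc[0]
        rna_unreliable = bool(flags["short_orf_excluded"] or
                              flags["intron_rna_excluded"])
        ribo = _replicate_ratios(quant, gene_id, "ribo", cond_a, cond_b)
        rna = _replicate_ratios(quant, gene_id, "rna", cond_a, cond_b)
        n_pairs = min(len(ribo), len(rna))
        density = [r / s for r, s in zip(ribo, rna)]
        for assay, ratios in (("ribo", ribo), ("rna", rna),
                              ("density", density)):
            excluded = (assay != "ribo" and rna_unreliable) or not ratios
            reason = ""
            if assay != "ribo" and rna_unreliable:
                reason = ("short_orf" if flags["short_orf_excluded"]
                          else "intron")
            elif not ratios:
                reason = "no_valid_replicate_pairs"
            rows.append({
                "gene_id": gene_id, "assay": assay,
                "mean_ratio": float(np.mean(ratios)) if ratios else np.nan,
                "sem": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
                if len(ratios) > 1 else 0.0 if ratios else np.nan,
                "n_replicates": len(ratios) if assay != "density"
                else n_pairs,
                "excluded": excluded, "reason": reason})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional occupancy
# ---------------------------------------------------------------------------

def positional_occupancy(track: CoverageTrack, gene: GeneModel
                         ) -> pd.DataFrame:
    """Each CDS position's fraction of the ORF's total assigned reads.

    Positions are reported in genomic coordinates (1-based in the
    ``position_1based`` column); fractions sum to 1 provided the ORF has
    at least one read.
    """
    tpos = np.arange(gene.cds_length)
    gpos = gene.transcript_to_genomic(tpos)
    counts = track.counts[gene.strand][gpos].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{gene.gene_id}: no reads in ORF")
    return pd.DataFrame({
        "gene_id": gene.gene_id,
        "transcript_pos": tpos,
        "position_1based": gpos + 1,
        "strand": gene.strand,
        "count": counts.astype(int),
        "rpm": counts * 1e6 / track.nuclear_cds_reads,
        "fraction": counts / total})


# ---------------------------------------------------------------------------
# pause comparison
# ---------------------------------------------------------------------------

def pause_compare(comparisons: Sequence[Mapping[str, CoverageTrack]],
                  genes: Sequence[GeneModel],
                  min_rpm: float = 30.0, min_fold: float = 2.0,
                  min_comparisons: int = 2,
                  floor_mode: str = "all") -> pd.DataFrame:
    """Plastome-wide light-vs-dark comparison of positional occupancy.

    ``comparisons`` is a list of independent comparisons, each a mapping
    ``{"light": track, "dark": track}`` of (replicate-pooled) coverage
    tracks.  Per comparison and gene, each position's fractional occupancy
    is computed in both conditions; positions below ``min_rpm`` are
    discarded — in all conditions of the comparison under the default
    ``floor_mode="all"`` (one-sided application would bias toward
    flagging), or in any condition with ``floor_mode="any"``.  A position
    counts as changed when its light/dark fraction ratio exceeds
    ``min_fold`` (or falls below 1/``min_fold``); it is flagged when
    changed in at least ``min_comparisons`` comparisons.

    With a single comparison supplied, ratios are still reported but
    flagging is disabled (with a warning).
    """
    flag_enabled = len(comparisons) >= 2
    if not flag_enabled:
        logger.warning("pause_compare: single comparison supplied; "
                       "flagging disabled")
    per_pos: dict[tuple, dict] = {}
    for ci, comp in enumerate(comparisons):
        for gene in genes:
            tpos = np.arange(gene.cds_length)
            gpos = gene.transcript_to_genomic(tpos)
            frac, rpm_arr = {}, {}
            for cond, track in comp.items():
                counts = track.counts[gene.strand][gpos].astype(float)
                total = counts.sum()
                frac[cond] = counts / total if total else counts
                rpm_arr[cond] = counts * 1e6 / track.nuclear_cds_reads
            below = np.vstack([rpm_arr[c] < min_rpm for c in comp])
            discard = below.all(axis=0) if floor_mode == "all" else \
                below.any(axis=0)
            covered = np.zeros(gene.cds_length, dtype=bool)
            for c in comp:
                covered |= frac[c] > 0
            for i in np.flatnonzero(covered & ~discard):
                fl, fd = frac["light"][i], frac["dark"][i]
                ratio = np.inf if fd == 0 else fl / fd
                changed = ratio > min_fold or ratio < 1.0 / min_fold
                key = (gene.gene_id, int(gpos[i]), gene.strand)
                rec = per_pos.setdefault(key, {
                    "transcript_pos": int(tpos[i]), "ratios": {},
                    "frac_light": {}, "frac_dark": {}, "n_changed": 0,
                    "n_evaluated": 0})
                rec["ratios"][ci] = float(ratio)
                rec["frac_light"][ci] = float(fl)
                rec["frac_dark"][ci] = float(fd)
                rec["n_evaluated"] += 1
                rec["n_changed"] += int(changed)
    rows = []
    for (gene_id, pos, strand), rec in sorted(per_pos.items()):
        rows.append({
            "gene_id": gene_id, "position_1based": pos + 1,
            "strand": strand, "transcript_pos": rec["transcript_pos"],
            "n_comparisons_evaluated": rec["n_evaluated"],
            "n_comparisons_changed": rec["n_changed"],
            "max_ratio": max(rec["ratios"].values()),
            "min_ratio": min(rec["ratios"].values()),
            "flagged": flag_enabled and
            rec["n_changed"] >= min_comparisons})
    return pd.DataFrame(rows, columns=[
        "gene_id", "position_1based", "strand", "transcript_pos",
        "n_comparisons_evaluated", "n_comparisons_changed", "max_ratio",
        "min_ratio", "flagged"])
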