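"""Data-quality surfaces: footprint size distributions, 3-nt periodicity,
metagene profiles, CDS confinement, and replicate correlation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel
from .quantify import OffsetModel, assigned_positions

logger = logging.getLogger("chlororibo")


@dataclass
class FrameProfile:
    """Fraction of P-sites in each reading frame of the host CDS."""

    fractions: np.ndarray                      # shape (3,)
    n_reads: int
    per_length: dict[int, np.ndarray]
    region: str = "orf_body"

    def __post_init__(self) -> None:
        if self.n_reads and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("frame fractions must sum to 1")


def _psite_transcript_positions(footprints, genes, offsets):
    """(transcript position, length) of every P-site inside a CDS."""
    out_t, out_len, out_gene = [], [], []
    pos = assigned_positions(footprints, "p_site", offsets)
    seqids = footprints["seqid"].to_numpy()
    strands = footprints["strand"].to_numpy()
    lengths = footprints["length"].to_numpy()
    for g in genes:
        sel = (seqids == g.seqid) & (strands == g.strand)
        if not sel.any():
            continue
        t = g.genomic_to_transcript(pos[sel])
        inside = t >= 0
        out_t.append(t[inside])
        out_len.append(lengths[sel][inside])
        out_gene.extend([g.gene_id] * int(inside.sum()))
    if not out_t:
        return (np.empty(0, dtype=np.int64),) * 2 + ([],)
    return np.concatenate(out_t), np.concatenate(out_len), out_gene


# ---------------------------------------------------------------------------
# size distributions
# ---------------------------------------------------------------------------

def size_distribution(footprints: pd.DataFrame,
                      genes: Sequence[GeneModel] | None = None,
                      region: str = "all",
                      offsets: OffsetModel | None = None,
                      start_codons: int = 7,
                      site_positions: set[int] | None = None,
                      length_range: tuple[int, int] = (18, 40)
                      ) -> pd.DataFrame:
    """Histogram of footprint lengths, optionally restricted to a region.

    ``region``: ``all``; ``start_region`` (P-site in the first
    ``start_codons`` codons); ``orf_body`` (codon ``start_codons``+1 to
    stop); ``buildup_sites`` (3' end in ``site_positions``).
    """
    if region == "all":
        lengths = footprints["length"].to_numpy()
    elif region == "buildup_sites":
        from .quantify import three_prime_positions
        tp = three_prime_positions(footprints)
        lengths = footprints["length"].to_numpy()[
            np.isin(tp, list(site_positions or ()))]
    elif region in ("start_region", "orf_body"):
        t, lens, _ = _psite_transcript_positions(footprints, genes, offsets)
        cut = 3 * start_codons
        lengths = lens[t < cut] if region == "start_region" else \
            lens[t >= cut]
    else:
        raise ValueError(f"unknown region {region!r}")
    if lengths.size == 0:
        logger.warning("size_distribution: empty selection for region %r",
                       region)
    lo, hi = length_range
    idx = np.arange(lo, hi + 1)
    counts = np.bincount(np.clip(lengths, lo, hi) - lo,
                         minlength=idx.size) if lengths.size else \
        np.zeros(idx.size, dtype=int)
    frac = counts / counts.sum() if counts.sum() else np.zeros(idx.size)
    return pd.DataFrame({"length": idx, "count": counts, "fraction": frac})


# ---------------------------------------------------------------------------
# frame profile
# ---------------------------------------------------------------------------

def frame_profile(footprints: pd.DataFrame, genes: Sequence[GeneModel],
                  offsets: OffsetModel, region: str = "orf_body"
                  ) -> FrameProfile:
    """3-nt periodicity: distribution of P-site frames within host CDSs."""
    t, lens, _ = _psite_transcript_positions(footprints, genes, offsets)
    if t.size == 0:
        return FrameProfile(np.zeros(3), 0, {}, region)
    frames = t % 3
    overall = np.bincount(frames, minlength=3) / t.size
    per_length = {}
    for L in np.unique(lens):
        fl = frames[lens == L]
        per_length[int(L)] = np.bincount(fl, minlength=3) / fl.size
    return FrameProfile(overall, int(t.size), per_length, region)


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

def metagene(track: CoverageTrack, genes: Sequence[GeneModel],
             window: int = 50, anchor: str = "start") -> pd.DataFrame:
    """Mean per-gene-normalized coverage around start (or stop) codons.

    Each gene's coverage in the window is divided by that gene's mean CDS
    coverage before averaging, so highly expressed genes do not dominate;
    genes with zero CDS reads are excluded from the mean.
    """
    offsets = np.arange(-window, window + 1)
    profiles = []
    for g in genes:
        vals = track.counts[g.strand].astype(float)
        cds_pos = g.transcript_to_genomic(np.arange(g.cds_length))
        mean_cov = vals[cds_pos].mean()
        if mean_cov == 0:
            continue
        if anchor == "start":
            anchor_pos = g.start_codon_pos
        else:
            a, b = g.cds_segments[-1]
            anchor_pos = b - 1 if g.strand == "+" else a
        step = 1 if g.strand == "+" else -1
        pos = anchor_pos + step * offsets
        ok = (pos >= 0) & (pos < vals.size)
        prof = np.full(offsets.size, np.nan)
        prof[ok] = vals[pos[ok]] / mean_cov
        profiles.append(prof)
    if not profiles:
        return pd.DataFrame({"offset": offsets,
                             "mean_normalized_coverage": np.nan,
                             "n_genes": 0})
    arr = np.vstack(profiles)
    return pd.DataFrame({
        "offset": offsets,
        "mean_normalized_coverage": np.nanmean(arr, axis=0),
        "n_genes": np.sum(~np.isnan(arr), axis=0)})


# ---------------------------------------------------------------------------
# replicate correlation
# ---------------------------------------------------------------------------

def replicate_correlation(quant: pd.DataFrame, assay: str | None = None,
                          log_transform: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-gene RPKM between samples.

    Computed on untransformed RPKM by default; ``log_transform`` switches
    to log10(RPKM + 0.1) for robustness to the most abundant genes.
    """
    df = quant if assay is None else quant[quant["assay"] == assay]
    wide = df.pivot_table(index="gene_id", columns="sample_id",
                          values="rpkm")
    if len(wide.columns) < 2:
        raise ValueError("replicate_correlation needs >= 2 samples")
    if log_transform:
        wide = np.log10(wide + 0.1)
    return wide.corr(method="pearson")


# ---------------------------------------------------------------------------
# CDS confinement
# ---------------------------------------------------------------------------

def cds_confinement(footprints: pd.DataFrame, genes: Sequence[GeneModel],
                    chloro_seqid: str = "chloro",
                    position_semantics: str = "p_site_from_three_prime",
                    offsets: OffsetModel | None = None) -> float:
    """Fraction of chloroplast reads whose assigned position lies in a CDS.

    The default assignment is the P-site implied by the 3' end, so
    terminating ribosomes (whose 3' ends protrude past the stop codon)
    still count as CDS-confined.  Returns NaN (with a warning) when there
    are no chloroplast reads.
    """
    sel = footprints["seqid"].to_numpy() == chloro_seqid
    if not sel.any():
        logger.warning("cds_confinement: no chloroplast reads")
        return float("nan")
    sub = footprints.loc[sel]
    pos = assigned_positions(sub, position_semantics, offsets)
    strands = sub["strand"].to_numpy()
    inside = np.zeros(len(sub), dtype=bool)
    for g in genes:
        if g.seqid != chloro_seqid:
            continue
        on_strand = strands == g.strand
        inside[on_strand] |= g.genomic_to_transcript(
            pos[on_strand]) >= 0
    return float(inside.mean())
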