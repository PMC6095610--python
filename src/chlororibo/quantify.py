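"""Normalized quantification: P-site offset calibration, exclusion-window
read counting, RPKM, and per-position coverage tracks.

RPKM here is reads per kilobase of quantification segment per million reads
mapped to nuclear CDS.  Ribo-seq counting excludes reads whose assigned
position falls in the first 10 or last 30 nt of the segment (initiating and
terminating ribosomes); RNA-seq counts use the full CDS with the alignment
midpoint as the assigned position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GeneModel, SampleMeta

DEFAULT_EXCLUDE = (10, 30)     # nt trimmed from segment 5' / 3' (Ribo-seq)


class QuantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# P-site offsets
# ---------------------------------------------------------------------------

@dataclass
class OffsetModel:
    """Per-footprint-length 5'-to-P-site offsets with calibration support.

    Length classes whose support falls below ``min_support`` fall back to
    the modal (best-supported) offset; with no calibration at all a fixed
    default offset is used.
    """

    offsets: dict[int, int] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)
    fallback: int = 12
    min_support: int = 10

    def offset_for(self, length: int) -> int:
        off = self.offsets.get(int(length))
        if off is not None and self.support.get(int(length), 0) >= \
                self.min_support:
            return off
        return self.fallback

    def offsets_array(self, lengths: np.ndarray) -> np.ndarray:
        table = {int(k): self.offset_for(k) for k in np.unique(lengths)}
        return np.vectorize(table.__getitem__, otypes=[np.int64])(lengths)

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, self.offsets[k], self.support.get(k, 0))
                for k in sorted(self.offsets)]
        return pd.DataFrame(rows, columns=["length", "offset", "support"])


def five_prime_positions(df: pd.DataFrame) -> np.ndarray:
    return np.where(df["strand"].to_numpy() == "+",
                    df["start"].to_numpy(), df["end"].to_numpy() - 1)


def three_prime_positions(df: pd.DataFrame) -> np.ndarray:
    return np.where(df["strand"].to_numpy() == "+",
                    df["end"].to_numpy() - 1, df["start"].to_numpy())


def calibrate_offsets(footprints: pd.DataFrame, genes: Sequence[GeneModel],
                      max_offset: int = 30, min_support: int = 10,
                      fallback: int = 12,
                      peak_fraction: float = 0.3) -> OffsetModel:
    """Infer 5'-to-P-site offsets from 5'-end positions at start codons.

    For each footprint length, histogram the distance from 5' ends to
    annotated start codons (along the strand).  Ribosomes at codons 2, 3,
    ... contribute distances 3, 6, ... nt short of the true offset, but no
    footprint originates upstream of the ORF, so the offset is the largest
    distance still carrying substantial support (at least
    ``peak_fraction`` of the histogram peak — stray non-CDS reads stay
    below that).  Length classes with support below ``min_support`` fall
    back to the modal offset.
    """
    starts = {"+": sorted(g.start_codon_pos for g in genes
                          if g.strand == "+"),
              "-": sorted(g.start_codon_pos for g in genes
                          if g.strand == "-")}
    five = five_prime_positions(footprints)
    strands = footprints["strand"].to_numpy()
    lengths = footprints["length"].to_numpy()
    seqids = footprints["seqid"].to_numpy()
    gene_seqids = {g.seqid for g in genes}
    in_scope = np.isin(seqids, list(gene_seqids))

    model = OffsetModel(fallback=fallback, min_support=min_support)
    any_support = False
    for L in np.unique(lengths[in_scope]):
        sel = in_scope & (lengths == L)
        hist = np.zeros(max_offset + 1, dtype=np.int64)
        for strand, sign in (("+", 1), ("-", -1)):
            f = five[sel & (strands == strand)]
            for s in starts[strand]:
                # distance the 5' end sits upstream of this start codon
                delta = sign * (s - f)
                ok = (delta >= 0) & (delta <= max_offset)
                hist += np.bincount(delta[ok], minlength=max_offset + 1)
        if hist.sum() == 0:
            continue
        floor = max(2, int(np.ceil(peak_fraction * hist.max())))
        supported = np.flatnonzero(hist >= floor)
        off = int(supported.max())
        model.offsets[int(L)] = off
        model.support[int(L)] = int(hist[off])
        any_support = any_support or hist[off] >= min_support
    if not model.offsets or not any_support:
        raise QuantError(
            "no start-proximal reads support offset calibration; "
            "use a fixed-offset OffsetModel instead")
    # modal offset = offset of the best-supported length class
    modal_len = max(model.support, key=model.support.get)
    model.fallback = model.offsets[modal_len]
    return model


# ---------------------------------------------------------------------------
# assigned positions
# ---------------------------------------------------------------------------

def assigned_positions(df: pd.DataFrame, position_semantics: str,
                       offsets: OffsetModel | None = None,
                       three_prime_offset: int = 15) -> np.ndarray:
    """Single genomic position each read is assigned to.

    ``three_prime_end``: the biological 3' end.  ``p_site``: 5' end plus
    the per-length calibrated offset, along the strand.
    ``p_site_from_three_prime``: 3' end minus the fixed 3' offset
    (footprints translating the same codon share a 3'-end position
    regardless of length, so this needs no per-length model).
    ``midpoint``: the alignment midpoint (RNA-seq).
    """
    if position_semantics == "three_prime_end":
        return three_prime_positions(df)
    if position_semantics == "midpoint":
        return (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    if position_semantics == "p_site_from_three_prime":
        tp = three_prime_positions(df)
        return np.where(df["strand"].to_numpy() == "+",
                        tp - three_prime_offset, tp + three_prime_offset)
    if position_semantics == "p_site":
        if offsets is None:
            raise QuantError("p_site semantics requires an OffsetModel")
        off = offsets.offsets_array(df["length"].to_numpy())
        five = five_prime_positions(df)
        return np.where(df["strand"].to_numpy() == "+", five + off,
                        five - off)
    raise QuantError(f"unknown position_semantics {position_semantics!r}")


# ---------------------------------------------------------------------------
# counting and RPKM
# ---------------------------------------------------------------------------

def count_gene(footprints: pd.DataFrame, gene: GeneModel, assay: str = "ribo",
               position_semantics: str = "p_site",
               offsets: OffsetModel | None = None,
               exclude: tuple[int, int] = DEFAULT_EXCLUDE,
               excluded_positions: set[int] | None = None,
               three_prime_offset: int = 15) -> int | None:
    """Count reads assigned to the gene's eligible window.

    Ribo-seq: assigned position must lie inside the quantification segment
    minus the first ``exclude[0]`` and last ``exclude[1]`` transcript-
    orientation nucleotides.  RNA-seq: alignment midpoint anywhere in the
    CDS.  Returns ``None`` when the eligible window is empty (gene too
    short), in which case the caller should flag the gene.
    ``excluded_positions`` (genomic, same strand) are dropped on top of the
    window rule — the build-up-site exclusion used by the run-off analysis.
    """
    sel = (footprints["seqid"].to_numpy() == gene.seqid) & \
          (footprints["strand"].to_numpy() == gene.strand)
    if not sel.any():
        return 0 if _eligible_len(gene, assay, exclude) > 0 else None
    sub = footprints.loc[sel]
    if assay == "rna":
        pos = assigned_positions(sub, "midpoint")
        tpos = gene.genomic_to_transcript(pos)
        ok = tpos >= 0
    else:
        lo, hi = gene.quant_transcript_window()
        lo, hi = lo + exclude[0], hi - exclude[1]
        if hi <= lo:
            return None
        pos = assigned_positions(sub, position_semantics, offsets,
                                 three_prime_offset)
        tpos = gene.genomic_to_transcript(pos)
        ok = (tpos >= lo) & (tpos < hi)
    if excluded_positions:
        ok &= ~np.isin(pos, list(excluded_positions))
    return int(ok.sum())


def _eligible_len(gene, assay, exclude):
    if assay == "rna":
        return gene.cds_length
    return gene.quant_length - exclude[0] - exclude[1]


def rpkm(raw_count: int, gene: GeneModel, nuclear_cds_reads: int,
         use_trimmed_length: bool = False,
         exclude: tuple[int, int] = DEFAULT_EXCLUDE) -> float:
    """reads / (segment kb) / (million nuclear-CDS reads).

    Length normalization uses the full quantification-segment length by
    default; ``use_trimmed_length`` switches to the exclusion-trimmed
    length instead.
    """
    if nuclear_cds_reads <= 0:
        raise QuantError("nuclear_cds_reads must be > 0 for RPKM")
    seg_nt = gene.quant_length
    if use_trimmed_length:
        seg_nt -= exclude[0] + exclude[1]
    return raw_count / (seg_nt / 1000.0) / (nuclear_cds_reads / 1e6)


def count_nuclear_cds(footprints: pd.DataFrame,
                      genes: Sequence[GeneModel]) -> int:
    """Reads whose midpoint lies in a nuclear CDS — the RPKM denominator."""
    n = 0
    for g in genes:
        sel = footprints["seqid"].to_numpy() == g.seqid
        if not sel.any():
            continue
        mids = assigned_positions(footprints.loc[sel], "midpoint")
        n += int((g.genomic_to_transcript(mids) >= 0).sum())
    return n


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def coverage_track(footprints: pd.DataFrame, seqid: str, ref_length: int,
                   nuclear_cds_reads: int,
                   position_semantics: str = "three_prime_end",
                   offsets: OffsetModel | None = None) -> CoverageTrack:
    """Per-position assigned-end counts for one reference, per strand.

    ``track.rpm(strand)[pos] = count * 1e6 / nuclear_cds_reads``; summing
    counts recovers the integer number of assigned reads exactly.
    """
    counts = {}
    for strand in "+-":
        sel = (footprints["seqid"].to_numpy() == seqid) & \
              (footprints["strand"].to_numpy() == strand)
        sub = footprints.loc[sel]
        pos = assigned_positions(sub, position_semantics, offsets)
        pos = pos[(pos >= 0) & (pos < ref_length)]
        counts[strand] = np.bincount(pos, minlength=ref_length).astype(
            np.int64)
    return CoverageTrack(seqid, counts, nuclear_cds_reads,
                         position_semantics)


def pool_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    pooled = tracks[0]
    for t in tracks[1:]:
        pooled = pooled.add(t)
    return pooled


# ---------------------------------------------------------------------------
# gene x sample table
# ---------------------------------------------------------------------------

def quant_table(samples: Mapping[str, tuple[SampleMeta, pd.DataFrame]],
                genes: Sequence[GeneModel],
                nuclear_genes: Sequence[GeneModel],
                position_semantics: str = "p_site",
                offsets_by_sample: Mapping[str, OffsetModel] | None = None,
                exclude: tuple[int, int] = DEFAULT_EXCLUDE,
                min_orf_len: int = 150) -> pd.DataFrame:
    """Build the long gene x sample table of counts and RPKM.

    One row per (gene, sample) with the raw count, RPKM, and the flags the
    comparison stages act on (``short_orf_excluded``: CDS below
    ``min_orf_len``; ``intron_rna_excluded``: intron-containing gene, whose
    mRNA level cannot be measured confidently).
    """
    rows = []
    for sid, (meta, df) in samples.items():
        nuc = count_nuclear_cds(df, nuclear_genes)
        offsets = (offsets_by_sample or {}).get(sid)
        semantics = position_semantics if meta.assay == "ribo" else "midpoint"
        for gene in genes:
            n = count_gene(df, gene, meta.assay, semantics, offsets, exclude)
            rows.append({
                "gene_id": gene.gene_id, "sample_id": sid,
                "assay": meta.assay, "condition": meta.condition,
                "timepoint_min": meta.timepoint_min,
                "treatment": meta.treatment, "replicate": meta.replicate,
                "count": n if n is not None else np.nan,
                "rpkm": rpkm(n, gene, nuc) if n is not None else np.nan,
                "short_orf_excluded": gene.cds_length < min_orf_len,
                "intron_rna_excluded": gene.has_intron,
                "window_undefined": n is None,
                "nuclear_cds_reads": nuc,
            })
    return pd.DataFrame(rows)
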