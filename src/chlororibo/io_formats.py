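"""Readers, writers and the shared coordinate/record model.

All internal coordinates are 0-based half-open on the genomic (plus) strand.
Written genomic reports (build-up site tables, pause tables) are 1-based;
GFF3 round-trips through the usual 1-based closed convention; bedGraph stays
0-based half-open.  The biological 3' end of an aligned fragment is
``end - 1`` on the plus strand and ``start`` on the minus strand.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chlororibo")

#: column order of the BED-like footprint/alignment table
FOOTPRINT_COLUMNS = ["seqid", "start", "end", "sample_id", "length", "strand"]

#: default mapping from reference-sequence name to compartment
DEFAULT_COMPARTMENT_MAP = {"chloro": "chloroplast", "nuclear": "nuclear"}


class AnnotationError(ValueError):
    """Malformed annotation input or an override naming an unknown gene."""


class FootprintError(ValueError):
    """Malformed alignment input (e.g. an unknown reference name)."""


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def gff3_to_internal(start_1based: int, end_closed: int) -> tuple[int, int]:
    """GFF3 1-based closed interval -> internal 0-based half-open."""
    return start_1based - 1, end_closed


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open interval -> GFF3 1-based closed."""
    return start + 1, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene's CDS geometry plus the segment used for quantification.

    ``cds_segments`` are genomic 0-based half-open intervals ordered 5'->3'
    in transcript orientation (for minus-strand genes the first segment is
    therefore the one with the largest genomic coordinates).
    ``quant_segment`` is the interval Ribo-seq RPKM is computed from: the
    full CDS for single-exon genes, the last exon for intron-containing
    genes, or a per-gene override (the rps12-style exception).
    """

    gene_id: str
    seqid: str
    strand: str
    cds_segments: list[tuple[int, int]]
    quant_segment: tuple[int, int] | None = None
    category: str = "other"
    has_intron: bool = False
    short_orf: bool = False
    not_multiple_of_three: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        for a, b in self.cds_segments:
            if b <= a:
                raise AnnotationError(f"{self.gene_id}: empty segment {a}:{b}")
        gs = sorted(self.cds_segments)
        for (a1, b1), (a2, b2) in zip(gs, gs[1:]):
            if a2 < b1:
                raise AnnotationError(f"{self.gene_id}: overlapping CDS segments")
        self.has_intron = self.has_intron or len(self.cds_segments) > 1
        if self.quant_segment is None:
            self.quant_segment = self.cds_segments[-1]
        qa, qb = self.quant_segment
        if not any(a <= qa and qb <= b for a, b in self.cds_segments):
            raise AnnotationError(
                f"{self.gene_id}: quant_segment not contained in a CDS segment")
        if (qb - qa) % 3 != 0:
            self.not_multiple_of_three = True

    # -- geometry ----------------------------------------------------------
    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def quant_length(self) -> int:
        a, b = self.quant_segment
        return b - a

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        a, b = self.cds_segments[0]
        return a if self.strand == "+" else b - 1

    def segments_transcript_order(self) -> list[tuple[int, int]]:
        return list(self.cds_segments)

    def genomic_to_transcript(self, pos: int | np.ndarray):
        """Map genomic position(s) to transcript (spliced CDS) position.

        Returns -1 for positions outside the CDS.  Vectorised over arrays.
        """
        pos = np.asarray(pos)
        out = np.full(pos.shape, -1, dtype=np.int64)
        offset = 0
        for a, b in self.cds_segments:
            inside = (pos >= a) & (pos < b)
            if self.strand == "+":
                out = np.where(inside, offset + (pos - a), out)
            else:
                out = np.where(inside, offset + (b - 1 - pos), out)
            offset += b - a
        return out if out.shape else int(out)

    def transcript_to_genomic(self, tpos: int | np.ndarray):
        """Inverse of :meth:`genomic_to_transcript` (CDS positions only)."""
        tpos = np.asarray(tpos)
        out = np.full(tpos.shape, -1, dtype=np.int64)
        offset = 0
        for a, b in self.cds_segments:
            seg_len = b - a
            inside = (tpos >= offset) & (tpos < offset + seg_len)
            if self.strand == "+":
                out = np.where(inside, a + (tpos - offset), out)
            else:
                out = np.where(inside, b - 1 - (tpos - offset), out)
            offset += seg_len
        return out if out.shape else int(out)

    def quant_transcript_window(self) -> tuple[int, int]:
        """Transcript coordinates [lo, hi) spanned by the quant segment."""
        a, b = self.quant_segment
        if self.strand == "+":
            lo = int(self.genomic_to_transcript(a))
        else:
            lo = int(self.genomic_to_transcript(b - 1))
        return lo, lo + self.quant_length


@dataclass(frozen=True)
class FootprintRecord:
    """A single aligned footprint; bulk data flows as a DataFrame with
    :data:`FOOTPRINT_COLUMNS`."""

    compartment: str
    strand: str
    start: int
    end: int
    length: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != self.length:
            raise FootprintError("end - start must equal length")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    assay: str          # ribo | rna
    condition: str      # light | dark
    timepoint_min: float = 0.0
    treatment: str = "none"   # none | lincomycin
    replicate: int = 1


@dataclass
class CoverageTrack:
    """Per-position assigned-end counts on one reference, both strands.

    Raw integer counts are stored; ``rpm`` views them as reads per million
    reads mapped to nuclear CDS, the normalization every positional analysis
    in this package uses.
    """

    seqid: str
    counts: dict[str, np.ndarray]
    nuclear_cds_reads: int
    position_semantics: str = "three_prime_end"

    def rpm(self, strand: str) -> np.ndarray:
        if self.nuclear_cds_reads <= 0:
            raise ValueError("nuclear_cds_reads must be positive for RpM")
        return self.counts[strand] * (1e6 / self.nuclear_cds_reads)

    @property
    def total_assigned(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        """Pool two tracks (counts and normalization denominators add)."""
        return CoverageTrack(
            self.seqid,
            {s: self.counts[s] + other.counts[s] for s in self.counts},
            self.nuclear_cds_reads + other.nuclear_cds_reads,
            self.position_semantics,
        )


# ---------------------------------------------------------------------------
# annotation reading
# ---------------------------------------------------------------------------

def _segments_in_transcript_order(segs: list[tuple[int, int]], strand: str):
    return sorted(segs, reverse=(strand == "-"))


def _apply_quant_rule(gene_id, segs_tx, overrides) -> tuple[int, int]:
    if overrides and gene_id in overrides:
        ov = overrides[gene_id]
        if isinstance(ov, int):
            if not 1 <= ov <= len(segs_tx):
                raise AnnotationError(
                    f"override for {gene_id}: exon {ov} of {len(segs_tx)}")
            return segs_tx[ov - 1]
        return tuple(ov)
    return segs_tx[-1] if len(segs_tx) > 1 else segs_tx[0]


def read_annotation(path: str | os.PathLike,
                    overrides: Mapping[str, int | tuple[int, int]] | None = None,
                    min_orf_len: int = 150) -> list[GeneModel]:
    """Read a GFF3 or flat-TSV annotation into :class:`GeneModel` records.

    Intron-containing genes get ``quant_segment = last exon`` (transcript
    orientation) unless overridden; ``overrides`` maps gene id to a 1-based
    exon number in transcript order, or to an explicit (start, end) interval.
    Genes shorter than ``min_orf_len`` are flagged ``short_orf``.
    """
    path = os.fspath(path)
    if path.endswith((".gff", ".gff3")):
        genes = _read_gff3(path)
    else:
        genes = _read_annotation_tsv(path)
    if overrides:
        known = {g for g, *_ in genes}
        for gid in overrides:
            if gid not in known:
                raise AnnotationError(f"override names unknown gene {gid!r}")
    out = []
    for gene_id, seqid, strand, segs, category in genes:
        segs_tx = _segments_in_transcript_order(segs, strand)
        quant = _apply_quant_rule(gene_id, segs_tx, overrides)
        gm = GeneModel(gene_id, seqid, strand, segs_tx, quant, category)
        gm.short_orf = gm.cds_length < min_orf_len
        out.append(gm)
    return out


def _read_gff3(path):
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene", order_by="start"):
        segs = []
        for cds in db.children(gene, featuretype="CDS", order_by="start"):
            segs.append(gff3_to_internal(cds.start, cds.end))
        if not segs:
            continue
        category = gene.attributes.get("category", ["other"])[0]
        genes.append((gene.id, gene.seqid, gene.strand, segs, category))
    return genes


def _read_annotation_tsv(path):
    """Flat table: gene_id, seqid, strand, segments, [category].

    ``segments`` is ``start:end`` pairs (0-based half-open) joined by ``;``
    in transcript order.
    """
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("gene_id", "seqid", "strand", "segments"):
            if req not in idx:
                raise AnnotationError(f"annotation TSV missing column {req!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                segs = []
                for part in f[idx["segments"]].split(";"):
                    a, b = part.split(":")
                    segs.append((int(a), int(b)))
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed coordinates "
                    f"{f[idx['segments']]!r}") from exc
            category = f[idx["category"]] if "category" in idx and \
                len(f) > idx["category"] else "other"
            genes.append((f[idx["gene_id"]], f[idx["seqid"]],
                          f[idx["strand"]], segs, category))
    return genes


def write_annotation_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gmin = min(a for a, _ in g.cds_segments)
            gmax = max(b for _, b in g.cds_segments)
            s1, e1 = internal_to_gff3(gmin, gmax)
            fh.write(f"{g.seqid}\tchlororibo\tgene\t{s1}\t{e1}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};category={g.category}\n")
            for i, (a, b) in enumerate(sorted(g.cds_segments)):
                s1, e1 = internal_to_gff3(a, b)
                fh.write(f"{g.seqid}\tchlororibo\tCDS\t{s1}\t{e1}\t.\t"
                         f"{g.strand}\t0\tID={g.gene_id}.cds{i};"
                         f"Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# footprint reading
# ---------------------------------------------------------------------------

def read_footprints(path: str | os.PathLike,
                    length_min: int = 18,
                    length_max: int = 40,
                    valid_refs: Iterable[str] | None = None,
                    sample_id: str | None = None) -> tuple[pd.DataFrame, int]:
    """Read aligned footprints, dropping records outside the length bounds.

    Accepts SAM/BAM (via pysam) or the 6-column BED-like TSV written by this
    package.  Returns ``(frame, n_dropped)`` where the frame has
    :data:`FOOTPRINT_COLUMNS`; retained + dropped always equals the number
    of mapped input records.
    """
    path = os.fspath(path)
    if path.endswith((".sam", ".bam")):
        df = _read_sam(path, sample_id or os.path.basename(path))
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
        if missing:
            raise FootprintError(f"{path}: missing columns {missing}")
    if valid_refs is not None:
        valid = set(valid_refs)
        bad = set(df["seqid"].unique()) - valid
        if bad:
            raise FootprintError(
                f"unknown reference name(s) {sorted(bad)}; "
                f"valid references: {sorted(valid)}")
    keep = (df["length"] >= length_min) & (df["length"] <= length_max)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_footprints(%s): dropped %d/%d reads outside "
                    "[%d, %d] nt", path, dropped, len(df), length_min,
                    length_max)
    return df.loc[keep].reset_index(drop=True), dropped


def _read_sam(path, sample_id):
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(path, mode) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            start, end = aln.reference_start, aln.reference_end
            rows.append((aln.reference_name, start, end, sample_id,
                         end - start, "-" if aln.is_reverse else "+"))
    return pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)


def write_footprints(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FOOTPRINT_COLUMNS)


def compartment_of(df: pd.DataFrame,
                   compartment_map: Mapping[str, str] | None = None
                   ) -> pd.Series:
    cmap = dict(compartment_map or DEFAULT_COMPARTMENT_MAP)
    return df["seqid"].map(lambda s: cmap.get(s, "other"))


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = [SampleMeta(str(r.sample_id), r.assay, r.condition,
                        float(r.timepoint_min), r.treatment, int(r.replicate))
             for r in df.itertuples()]
    keys = [(m.assay, m.condition, m.timepoint_min, m.treatment, m.replicate)
            for m in metas]
    if len(set(keys)) != len(keys):
        raise AnnotationError("sample sheet rows are not unique on "
                              "(assay, condition, timepoint, treatment, "
                              "replicate)")
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path) -> None:
    pd.DataFrame([m.__dict__ for m in metas]).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------------
# table / track output
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path_prefix: str,
                   normalized: bool = True) -> list[str]:
    """Write one bedGraph per strand (0-based half-open intervals).

    Adjacent equal-valued positions are merged into one interval; zeros are
    omitted.  Returns the written paths.
    """
    paths = []
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        values = track.rpm(strand) if normalized else \
            track.counts[strand].astype(float)
        path = f"{path_prefix}.{suffix}.bedGraph"
        with open(path, "w") as fh:
            nz = np.flatnonzero(values)
            if nz.size:
                # break runs where the value changes or positions skip
                breaks = np.flatnonzero(
                    (np.diff(nz) != 1) |
                    (np.diff(values[nz]) != 0)) + 1
                for chunk in np.split(nz, breaks):
                    fh.write(f"{track.seqid}\t{chunk[0]}\t{chunk[-1] + 1}\t"
                             f"{values[chunk[0]]:.6g}\n")
        paths.append(path)
    return paths


def read_bedgraph(path, seqid: str, length: int) -> np.ndarray:
    values = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, a, b, v = line.split("\t")
            if chrom != seqid:
                continue
            values[int(a):int(b)] = float(v)
    return values


def write_tables(results: Mapping[str, pd.DataFrame], out_dir) -> dict:
    """Write each named DataFrame as ``<name>.tsv`` under ``out_dir``.

    Floats are written with 6 significant digits so a round-trip read
    reproduces values to that precision.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for name, df in results.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[name] = path
    return written
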