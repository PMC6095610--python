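"""Independent reference implementations used only to check the package.

These deliberately share no code with chlororibo's counting or run-off
paths: plain per-read Python loops and a per-ribosome stochastic walker.
"""

import numpy as np


def genomic_to_transcript_slow(gene, gpos):
    """Per-position segment walk (no vectorization, no shared helpers)."""
    offset = 0
    for a, b in gene.cds_segments:
        if a <= gpos < b:
            if gene.strand == "+":
                return offset + (gpos - a)
            return offset + (b - 1 - gpos)
        offset += b - a
    return None


def assigned_position_slow(row, semantics, offset_table=None, d3=15):
    seqid, start, end, length, strand = row
    if strand == "+":
        five, three = start, end - 1
    else:
        five, three = end - 1, start
    if semantics == "three_prime_end":
        return three
    if semantics == "midpoint":
        return (start + end) // 2
    if semantics == "p_site":
        off = offset_table[length]
        return five + off if strand == "+" else five - off
    if semantics == "p_site_from_three_prime":
        return three - d3 if strand == "+" else three + d3
    raise ValueError(semantics)


def count_gene_slow(rows, gene, assay="ribo", semantics="p_site",
                    offset_table=None, exclude=(10, 30)):
    """Brute-force per-read tally of the exclusion-window count."""
    # transcript span of the quantification segment
    qa, qb = gene.quant_segment
    anchor = qa if gene.strand == "+" else qb - 1
    qlo = genomic_to_transcript_slow(gene, anchor)
    qhi = qlo + (qb - qa)
    n = 0
    for row in rows:
        seqid, start, end, length, strand = row
        if seqid != gene.seqid or strand != gene.strand:
            continue
        if assay == "rna":
            pos = assigned_position_slow(row, "midpoint")
            if genomic_to_transcript_slow(gene, pos) is not None:
                n += 1
            continue
        pos = assigned_position_slow(row, semantics, offset_table)
        t = genomic_to_transcript_slow(gene, pos)
        if t is None:
            continue
        if qlo + exclude[0] <= t < qhi - exclude[1]:
            n += 1
    return n


def coverage_track_slow(rows, seqid, ref_length, semantics="three_prime_end",
                        offset_table=None):
    """Brute-force per-strand tally of assigned positions."""
    counts = {"+": np.zeros(ref_length, dtype=int),
              "-": np.zeros(ref_length, dtype=int)}
    for row in rows:
        if row[0] != seqid:
            continue
        pos = assigned_position_slow(row, semantics, offset_table)
        if 0 <= pos < ref_length:
            counts[row[4]][pos] += 1
    return counts


def walker_percent_remaining(n_codons, body_lo, block, rate, t, n_walkers,
                             rng, n_batches=20):
    """Single-ribosome stochastic run-off oracle.

    Ribosomes start uniformly over the ORF's codons; those past the block
    codon advance by a Poisson(rate*t) number of codons and leave past the
    stop.  Returns (percent remaining in the body [body_lo, n_codons), MC
    standard error from batch means).
    """
    c0 = rng.integers(0, n_codons, size=n_walkers)
    steps = rng.poisson(rate * t, size=n_walkers)
    c1 = np.where(c0 >= block, c0 + steps, c0)
    in_body_0 = (c0 >= body_lo) & (c0 < n_codons)
    in_body_t = (c1 >= body_lo) & (c1 < n_codons) & (c0 >= block)
    # frozen sub-block ribosomes never sit in the body (body_lo >= block)
    est = 100.0 * in_body_t.sum() / in_body_0.sum()
    batch = []
    for chunk0, chunkt in zip(np.array_split(in_body_0, n_batches),
                              np.array_split(in_body_t, n_batches)):
        if chunk0.sum():
            batch.append(100.0 * chunkt.sum() / chunk0.sum())
    se = np.std(batch, ddof=1) / np.sqrt(len(batch))
    return est, se
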