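"""Readers/writers for the plain-text formats the pipeline consumes and emits.

Aligned 3'-end reads travel either as SAM (soft-clipped tails parsed from
the alignment record via pysam) or as a 6-column TSV dialect
(read_id, chrom, strand, aln_start, aln_end, tail_seq) that the simulator
emits; both carry the same information.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping

import pandas as pd

from .genome import revcomp
from .passreads import AlignedRead, PassRead, PolyASite

READS_TSV_COLUMNS = ["read_id", "chrom", "strand", "aln_start", "aln_end", "tail_seq"]


def write_reads_tsv(path, reads: Iterable[AlignedRead]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(READS_TSV_COLUMNS)
        for r in reads:
            w.writerow([r.read_id, r.chrom, r.strand, r.aln_start, r.aln_end, r.tail_seq])


def read_reads_tsv(path) -> list[AlignedRead]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != READS_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for row in reader:
            rid, chrom, strand, s, e, tail = (row + [""])[:6]
            out.append(AlignedRead(rid, chrom, strand, int(s), int(e), tail))
    return out


def write_sam(path, reads: Iterable[AlignedRead], genome) -> None:
    """Write aligned reads as plain SAM with the 3' tail soft-clipped.

    SEQ is reported on the forward genome strand, so for minus-strand reads
    the tail appears reverse-complemented ahead of the aligned block with a
    leading soft clip.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in reads:
            block = genome.fetch(r.chrom, r.aln_start, r.aln_end)
            n_block, n_tail = len(block), len(r.tail_seq)
            if r.strand == "+":
                flag = 0
                seq = block + r.tail_seq
                cigar = f"{n_block}M{n_tail}S" if n_tail else f"{n_block}M"
            else:
                flag = 16
                seq = revcomp(r.tail_seq) + block
                cigar = f"{n_tail}S{n_block}M" if n_tail else f"{n_block}M"
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.aln_start + 1}\t255\t{cigar}\t"
                f"*\t0\t0\t{seq}\t*\n"
            )


def read_sam(path) -> list[AlignedRead]:
    """Parse aligned reads from SAM/BAM, extracting the 3'-side soft clip."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence or ""
            cig = rec.cigartuples or []
            if rec.is_reverse:
                strand = "-"
                tail = revcomp(seq[: cig[0][1]]) if cig and cig[0][0] == 4 else ""
            else:
                strand = "+"
                tail = seq[-cig[-1][1] :] if cig and cig[-1][0] == 4 else ""
            out.append(
                AlignedRead(rec.query_name, rec.reference_name, strand,
                            rec.reference_start, rec.reference_end, tail)
            )
    return out


def read_aligned(path, fmt: str = "auto") -> list[AlignedRead]:
    fmt = str(fmt)
    if fmt == "auto":
        fmt = "sam" if str(path).endswith((".sam", ".bam")) else "tsv"
    if fmt == "sam":
        return read_sam(path)
    if fmt == "tsv":
        return read_reads_tsv(path)
    raise ValueError(f"unknown reads format {fmt!r}")


def write_pass_bed(path, pass_reads: Iterable[PassRead]) -> None:
    """PASS reads as BED6; score carries the non-genomic A count."""
    with open(path, "w") as fh:
        for pr in pass_reads:
            fh.write(
                f"{pr.chrom}\t{pr.pa_site}\t{pr.pa_site + 1}\t{pr.read_id}\t"
                f"{pr.nongenomic_a}\t{pr.strand}\n"
            )


def sites_frame(sites: Iterable[PolyASite], samples: list[str]) -> pd.DataFrame:
    rows = [
        {"chrom": s.chrom, "strand": s.strand, "position": s.position,
         **{f"count_{name}": s.counts.get(name, 0) for name in samples}}
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "position"] + [f"count_{s}" for s in samples]
    )


def write_tsv(path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def totals_from_report(report: pd.DataFrame) -> Mapping[str, int]:
    return dict(zip(report["library"], report["pass_reads"]))
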