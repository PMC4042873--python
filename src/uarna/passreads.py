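"""Poly(A)-site-supporting (PASS) read calling and poly(A)-site clustering.

A 3'-end sequencing read evidences a cleavage/polyadenylation site when its
3' soft-clipped tail carries adenosines that are *non-genomic*, i.e. not
templated by the reference downstream of the alignment.  Non-genomic content
is determined by the longest templated prefix: the tail is compared
base-for-base with the reference continuation past the alignment end
(reverse-complemented for minus-strand reads); whatever follows the first
mismatch is non-genomic.  A read is PASS iff its non-genomic tail contains
at least ``min_nongenomic_a`` As (default 2) and the whole tail is
A-rich (A fraction >= ``min_a_fraction``), which screens out soft clips that
are adapter or mismatch artifacts rather than poly(A) tails.

The poly(A) site of a PASS read is its 3'-most aligned base, advanced past
any templated prefix of the tail.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .genome import revcomp

DEFAULT_MIN_NONGENOMIC_A = 2
DEFAULT_MIN_A_FRACTION = 0.8
DEFAULT_CLUSTER_WINDOW = 24


class AlignedRead(NamedTuple):
    """An aligned 3'-end read: aligned block plus the 3' soft-clipped tail.

    ``tail_seq`` is in read orientation (transcript direction) and may be
    empty; coordinates are 0-based half-open on the forward genome strand.
    """

    read_id: str
    chrom: str
    strand: str
    aln_start: int
    aln_end: int
    tail_seq: str


class PassRead(NamedTuple):
    """A PASS read: poly(A) site plus its non-genomic A count."""

    read_id: str
    chrom: str
    strand: str
    pa_site: int
    nongenomic_a: int


class PolyASite(NamedTuple):
    """A clustered cleavage site with per-sample read counts."""

    chrom: str
    strand: str
    position: int
    counts: dict  # sample -> read count

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def call_pass(
    read: AlignedRead,
    genome,
    min_nongenomic_a: int = DEFAULT_MIN_NONGENOMIC_A,
    min_a_fraction: float = DEFAULT_MIN_A_FRACTION,
) -> PassRead | None:
    """Classify one aligned read; return a :class:`PassRead` or ``None``.

    The reference continuation is read strand-aware: downstream of
    ``aln_end`` for + reads, upstream of ``aln_start`` (reverse-complemented)
    for - reads.  Where the chromosome ends mid-tail the remaining tail bases
    count as non-genomic.  N in the tail never matches the reference and
    never counts as A.
    """
    tail = read.tail_seq.upper()
    if not tail:
        return None
    n = len(tail)
    if read.strand == "+":
        ref = genome.fetch(read.chrom, read.aln_end, read.aln_end + n)
    else:
        ref = revcomp(genome.fetch(read.chrom, read.aln_start - n, read.aln_start))
    k = 0
    for t, r in zip(tail, ref):
        if t != r or t == "N":
            break
        k += 1
    nongenomic = tail[k:]
    if nongenomic.count("A") < min_nongenomic_a:
        return None
    if tail.count("A") / n < min_a_fraction:
        return None
    if read.strand == "+":
        pa_site = read.aln_end - 1 + k
    else:
        pa_site = read.aln_start - k
    return PassRead(read.read_id, read.chrom, read.strand, pa_site, nongenomic.count("A"))


def call_pass_library(
    reads: Iterable[AlignedRead],
    genome,
    min_nongenomic_a: int = DEFAULT_MIN_NONGENOMIC_A,
    min_a_fraction: float = DEFAULT_MIN_A_FRACTION,
) -> tuple[list[PassRead], int]:
    """Call PASS over a library; returns (pass_reads, n_input_reads)."""
    out = []
    n_input = 0
    for read in reads:
        n_input += 1
        pr = call_pass(read, genome, min_nongenomic_a, min_a_fraction)
        if pr is not None:
            out.append(pr)
    return out, n_input


def cluster_sites(
    pass_reads: Mapping[str, Sequence[PassRead]],
    window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[PolyASite]:
    """Single-linkage clustering of poly(A) sites within ``window`` bp.

    Positions on the same chromosome and strand whose adjacent gaps are
    <= ``window`` merge into one site.  The representative position is the
    member with the highest pooled count (ties broken 5'-most, strand-aware);
    per-sample counts are summed over members, so total reads are conserved.
    Output is sorted by (chrom, strand, position) and independent of input
    order.
    """
    samples = list(pass_reads)
    by_locus: dict[tuple[str, str], dict[int, dict[str, int]]] = {}
    for sample in samples:
        for pr in pass_reads[sample]:
            pos_counts = by_locus.setdefault((pr.chrom, pr.strand), {})
            cnt = pos_counts.setdefault(pr.pa_site, {s: 0 for s in samples})
            cnt[sample] += 1

    sites: list[PolyASite] = []
    for (chrom, strand), pos_counts in by_locus.items():
        positions = sorted(pos_counts)
        cluster: list[int] = []

        def _emit(members: list[int]):
            pooled = {p: sum(pos_counts[p].values()) for p in members}
            best = max(pooled.values())
            candidates = [p for p in members if pooled[p] == best]
            rep = min(candidates) if strand == "+" else max(candidates)
            counts = {s: sum(pos_counts[p][s] for p in members) for s in samples}
            sites.append(PolyASite(chrom, strand, rep, counts))

        for p in positions:
            if cluster and p - cluster[-1] > window:
                _emit(cluster)
                cluster = []
            cluster.append(p)
        if cluster:
            _emit(cluster)

    sites.sort(key=lambda s: (s.chrom, s.strand, s.position))
    return sites


def pass_report(
    input_counts: Mapping[str, int], pass_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-library tallies: input reads, PASS reads, PASS fraction."""
    rows = []
    for lib in input_counts:
        n_in = input_counts[lib]
        n_pass = pass_counts.get(lib, 0)
        frac = n_pass / n_in if n_in > 0 else math.nan
        rows.append({"library": lib, "input_reads": n_in, "pass_reads": n_pass,
                     "pass_fraction": frac})
    return pd.DataFrame(rows, columns=["library", "input_reads", "pass_reads", "pass_fraction"])
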