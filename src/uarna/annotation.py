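"""Gene models, 3' extension, and the strand-aware region index.

The analysis operates at gene level: transcripts sharing a gene identifier
are merged to the gene's maximal span before the transcription start site
(TSS) and 3'-extension logic run.  All coordinates are 0-based half-open
internally; BED input is consumed as-is, GTF is converted from 1-based
inclusive on load.

Two region classes drive read assignment:

* the *sense region* of a gene — its merged span, optionally extended by
  ``extension`` bp past its 3' end when no other same-strand gene occupies
  the would-be extension interval (all-or-nothing, clipped at chromosome
  edges);
* the *uaRNA window* — the ``ua_window`` bp immediately upstream of the TSS
  on the antisense strand, half-open at the TSS, where upstream antisense
  (PROMPT) poly(A) sites are expected.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_EXTENSION = 4000
DEFAULT_UA_WINDOW = 2000


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One protein-coding gene: merged span plus extended sense boundaries.

    ``start``/``end`` are the native merged span; ``ext_start``/``ext_end``
    bound the sense region after 3' extension (equal to the native span
    until :func:`extend_three_prime` runs).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ext_start: int = -1
    ext_end: int = -1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.ext_start < 0:
            object.__setattr__(self, "ext_start", self.start)
        if self.ext_end < 0:
            object.__setattr__(self, "ext_end", self.end)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def sense_region(self) -> tuple[int, int]:
        return (self.ext_start, self.ext_end)

    @property
    def extended_end(self) -> int:
        """Strand-aware 3' boundary after extension (half-open on +, closed on -)."""
        return self.ext_end if self.strand == "+" else self.ext_start


@dataclass(frozen=True, slots=True)
class UaWindow:
    """Antisense window upstream of a gene's TSS (half-open, TSS excluded)."""

    gene_id: str
    chrom: str
    strand: str  # opposite of the gene's strand
    start: int
    end: int


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def _iter_bed(stream: Iterable[str]):
    for line in stream:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 6:
            raise ValueError(f"BED record needs >=6 fields: {line!r}")
        yield f[3], f[0], f[5], int(f[1]), int(f[2])


def _iter_gtf(stream: Iterable[str]):
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"GTF record needs 9 fields: {line!r}")
        m = _GTF_GENE_ID.search(f[8])
        if not m:
            raise ValueError(f"GTF record without gene_id attribute: {line!r}")
        # GTF is 1-based inclusive -> 0-based half-open
        yield m.group(1), f[0], f[6], int(f[3]) - 1, int(f[4])


def load_gene_models(
    annotation: Iterable[str] | TextIO,
    genome_lengths: Mapping[str, int],
    fmt: str = "bed",
) -> list[GeneModel]:
    """Parse a BED(6/12) or GTF annotation into merged per-gene models.

    Transcripts of a gene (records sharing a name/gene_id) are merged to the
    min-start/max-end span.  Records on chromosomes absent from
    ``genome_lengths`` are dropped with a warning; a malformed strand or an
    empty interval raises.  Output is sorted by (chrom, start, gene_id).
    """
    it = _iter_bed(annotation) if fmt == "bed" else _iter_gtf(annotation)
    spans: dict[str, list] = {}
    for gene_id, chrom, strand, start, end in it:
        if chrom not in genome_lengths:
            logger.warning("skipping %s: unknown chromosome %s", gene_id, chrom)
            continue
        if strand not in ("+", "-"):
            raise ValueError(f"{gene_id}: strand must be + or -, got {strand!r}")
        if start >= end:
            raise ValueError(f"{gene_id}: start {start} >= end {end}")
        rec = spans.get(gene_id)
        if rec is None:
            spans[gene_id] = [chrom, strand, start, end]
        else:
            if rec[0] != chrom or rec[1] != strand:
                raise ValueError(f"{gene_id}: inconsistent chrom/strand across records")
            rec[2] = min(rec[2], start)
            rec[3] = max(rec[3], end)
    genes = [
        GeneModel(gene_id=g, chrom=c, strand=s, start=a, end=b)
        for g, (c, s, a, b) in spans.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def extend_three_prime(
    genes: list[GeneModel],
    genome_lengths: Mapping[str, int],
    extension: int = DEFAULT_EXTENSION,
) -> list[GeneModel]:
    """Extend each gene's 3' end by ``extension`` bp when unobstructed.

    The extension is granted in full iff no *other* gene on the same strand
    overlaps the would-be extension interval (all-or-nothing), and is clipped
    at chromosome edges.  Obstruction is tested against native spans, so the
    operation is idempotent.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(g.start, g.end, g.gene_id)

    out = []
    for g in genes:
        length = genome_lengths[g.chrom]
        tree = trees[(g.chrom, g.strand)]
        if g.strand == "+":
            lo, hi = g.end, min(g.end + extension, length)
        else:
            lo, hi = max(0, g.start - extension), g.start
        blocked = lo < hi and any(
            iv.data != g.gene_id for iv in tree.overlap(lo, hi)
        )
        if blocked or lo >= hi:
            out.append(dataclasses.replace(g, ext_start=g.start, ext_end=g.end))
        elif g.strand == "+":
            out.append(dataclasses.replace(g, ext_start=g.start, ext_end=hi))
        else:
            out.append(dataclasses.replace(g, ext_start=lo, ext_end=g.end))
    return out


class RegionIndex:
    """Strand-aware point/interval lookup of sense regions and uaRNA windows."""

    def __init__(self, genes: Iterable[GeneModel], windows: Iterable[UaWindow]):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.windows: list[UaWindow] = list(windows)
        self._sense: dict[tuple[str, str], IntervalTree] = {}
        self._ua: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            s, e = g.sense_region
            self._sense.setdefault((g.chrom, g.strand), IntervalTree()).addi(s, e, g.gene_id)
        for w in self.windows:
            if w.start < w.end:
                self._ua.setdefault((w.chrom, w.strand), IntervalTree()).addi(
                    w.start, w.end, w.gene_id
                )

    def has_chrom(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self._sense) or any(
            c == chrom for c, _ in self._ua
        )

    def sense_gene_ids(self, chrom: str, strand: str, pos: int) -> list[str]:
        tree = self._sense.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def sense_gene_ids_overlap(self, chrom: str, strand: str, start: int, end: int) -> list[str]:
        tree = self._sense.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def ua_gene_ids(self, chrom: str, strand: str, pos: int) -> list[str]:
        tree = self._ua.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def sense_regions(self):
        for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            s, e = g.sense_region
            yield g.chrom, s, e, g.gene_id, g.strand

    def ua_regions(self):
        for w in sorted(self.windows, key=lambda w: (w.chrom, w.start, w.gene_id)):
            yield w.chrom, w.start, w.end, w.gene_id, w.strand


def build_ua_windows(
    genes: Iterable[GeneModel],
    genome_lengths: Mapping[str, int],
    ua_window: int = DEFAULT_UA_WINDOW,
) -> list[UaWindow]:
    """The ``ua_window`` bp upstream of each TSS on the antisense strand.

    For a + gene with TSS t the window is [t-w, t) on -; for a - gene,
    [t+1, t+1+w) on +.  Clipped at chromosome edges.
    """
    if ua_window <= 0:
        raise ValueError("ua_window must be > 0")
    out = []
    for g in genes:
        length = genome_lengths[g.chrom]
        t = g.tss
        if g.strand == "+":
            w = UaWindow(g.gene_id, g.chrom, "-", max(0, t - ua_window), t)
        else:
            w = UaWindow(g.gene_id, g.chrom, "+", t + 1, min(length, t + 1 + ua_window))
        out.append(w)
    return out


def build_region_index(
    genes: list[GeneModel],
    genome_lengths: Mapping[str, int],
    ua_window: int = DEFAULT_UA_WINDOW,
    sense_includes_extension: bool = True,
) -> RegionIndex:
    """Build the lookup index used for read assignment.

    ``sense_includes_extension=False`` restricts sense regions (and hence the
    uaRNA exclusion rule) to native gene spans; the default treats the 3'
    extension as genic territory.
    """
    windows = build_ua_windows(genes, genome_lengths, ua_window)
    if sense_includes_extension:
        idx_genes = genes
    else:
        idx_genes = [
            dataclasses.replace(g, ext_start=g.start, ext_end=g.end) for g in genes
        ]
    return RegionIndex(idx_genes, windows)


def write_bed6(path, regions, score: int = 0) -> None:
    """Write (chrom, start, end, name, strand) tuples as 6-column BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
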