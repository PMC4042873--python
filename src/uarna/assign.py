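"""Sense / uaRNA assignment of PASS reads and per-gene count tables.

Assignment uses the poly(A) site of each PASS read (its strand-aware 3'
end) as the assignment coordinate, by default:

1. if the site lies inside exactly one gene's sense region on the read's
   strand, the read is *sense* for that gene; inside more than one,
   *ambiguous* (excluded from all counts);
2. otherwise, if the site lies in one or more uaRNA windows on the read's
   strand — and, per the exclusion rule, could not be sense-assigned to any
   gene — it is *uaRNA* for the window gene with the nearest TSS
   (lexicographically smallest gene_id on ties);
3. otherwise *unassigned*.

Sense assignment strictly precedes uaRNA.  An ``any_overlap`` mode that
tests the whole aligned block against sense regions instead of the poly(A)
site alone is available via ``aln_span``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .annotation import RegionIndex
from .passreads import PassRead

logger = logging.getLogger(__name__)

SENSE = "sense"
UARNA = "uaRNA"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
CATEGORIES = (SENSE, UARNA, AMBIGUOUS, UNASSIGNED)


class Assignment(NamedTuple):
    read_id: str
    gene_id: str | None
    category: str


def assign_read(
    read: PassRead,
    index: RegionIndex,
    aln_span: tuple[int, int] | None = None,
) -> Assignment:
    """Assign one PASS read; ``aln_span`` switches sense lookup to any-overlap."""
    if not index.has_chrom(read.chrom):
        logger.warning("read %s: chromosome %s absent from index", read.read_id, read.chrom)
        return Assignment(read.read_id, None, UNASSIGNED)
    if aln_span is None:
        sense_hits = index.sense_gene_ids(read.chrom, read.strand, read.pa_site)
    else:
        sense_hits = index.sense_gene_ids_overlap(read.chrom, read.strand, *aln_span)
    if len(sense_hits) == 1:
        return Assignment(read.read_id, sense_hits[0], SENSE)
    if len(sense_hits) > 1:
        return Assignment(read.read_id, None, AMBIGUOUS)
    ua_hits = index.ua_gene_ids(read.chrom, read.strand, read.pa_site)
    if ua_hits:
        gene_id = min(
            ua_hits, key=lambda g: (abs(read.pa_site - index.genes[g].tss), g)
        )
        return Assignment(read.read_id, gene_id, UARNA)
    return Assignment(read.read_id, None, UNASSIGNED)


def assign_sample(
    pass_reads: Sequence[PassRead],
    index: RegionIndex,
    mode: str = "pa_site",
    spans: Mapping[str, tuple[int, int]] | None = None,
) -> list[Assignment]:
    """Assign every PASS read of one sample.

    ``mode='any_overlap'`` requires ``spans`` mapping read_id to its aligned
    block; sense lookup then uses block overlap while uaRNA lookup stays on
    the poly(A) site.
    """
    if mode not in ("pa_site", "any_overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    out = []
    for pr in pass_reads:
        span = spans[pr.read_id] if mode == "any_overlap" else None
        out.append(assign_read(pr, index, aln_span=span))
    return out


def build_count_table(
    assignments: Mapping[str, Iterable[Assignment]],
    gene_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-gene sense/uaRNA counts, one row per gene, per-sample columns.

    Genes with zero reads everywhere are retained with zeros.  Columns are
    ``sense_<sample>`` and ``ua_<sample>``.
    """
    samples = list(assignments)
    if len(set(samples)) != len(samples):
        raise ValueError("sample name collision")
    gene_ids = list(gene_ids)
    table = pd.DataFrame(
        0,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"{cat}_{s}" for s in samples for cat in ("sense", "ua")],
        dtype=int,
    )
    for sample in samples:
        sense_col = table.columns.get_loc(f"sense_{sample}")
        ua_col = table.columns.get_loc(f"ua_{sample}")
        row_of = {g: i for i, g in enumerate(gene_ids)}
        for a in assignments[sample]:
            if a.category == SENSE:
                table.iat[row_of[a.gene_id], sense_col] += 1
            elif a.category == UARNA:
                table.iat[row_of[a.gene_id], ua_col] += 1
    return table


def rpm_normalize(table: pd.DataFrame, totals: Mapping[str, int]) -> pd.DataFrame:
    """Add reads-per-million columns; denominator is *total PASS reads*.

    RPM = count * 1e6 / total PASS reads of the sample (not assigned reads).
    """
    out = table.copy()
    for sample, total in totals.items():
        if total <= 0:
            raise ValueError(f"sample {sample}: total PASS reads must be > 0")
        for cat in ("sense", "ua"):
            col = f"{cat}_{sample}"
            if col in out.columns:
                out[f"{cat}_rpm_{sample}"] = out[col] * 1e6 / total
    return out


def category_tallies(assignments: Iterable[Assignment]) -> dict[str, int]:
    """Counts per category; always includes all four categories."""
    tally = {c: 0 for c in CATEGORIES}
    for a in assignments:
        tally[a.category] += 1
    return tally
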