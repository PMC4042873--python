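"""Site-level descriptive profiles.

Three views of the uaRNA poly(A)-site landscape:

* the distribution of uaRNA poly(A)-site distances from the host gene's TSS
  (distance measured upstream along the gene's orientation axis, strictly
  positive, half-open binning);
* nucleotide frequency profiles around poly(A) sites, reported on the
  transcribed strand of the cleaved RNA so the poly(A) signal (e.g. AATAAA)
  appears upstream of offset 0;
* the TSS-proximal antisense metagene: per-base RPM of uaRNA poly(A) sites
  over [-span, 0) relative to the TSS, aggregated over genes with uaRNA
  detected in either sample and lowess-smoothed (tricube-weighted local
  linear regression).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .annotation import GeneModel
from .genome import revcomp
from .passreads import PassRead, PolyASite

DEFAULT_FLANK = 50
DEFAULT_SPAN = 2000
DEFAULT_LOWESS_FRAC = 0.3
DEFAULT_LOWESS_IT = 0


def tss_distance(pos: int, gene: GeneModel) -> int:
    """Upstream distance of a genomic position from the gene's TSS.

    Positive for positions upstream of the TSS on the gene's orientation
    axis: (TSS - pos) for + genes, (pos - TSS) for - genes.
    """
    return gene.tss - pos if gene.strand == "+" else pos - gene.tss


def tss_distance_histogram(
    sites: Iterable[tuple[PolyASite, GeneModel]],
    max_dist: int = 2000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Histogram of uaRNA poly(A)-site distances from the TSS.

    ``sites`` pairs each uaRNA-assigned site with its host gene.  Bins are
    half-open [lo, hi); distances >= ``max_dist`` (or non-positive) are
    excluded.  Counts sites, not reads.
    """
    edges = np.arange(0, max_dist + bin_size, bin_size)
    dists = [
        d
        for site, gene in sites
        if 0 < (d := tss_distance(site.position, gene)) < max_dist
    ]
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n_sites": counts}
    )


def nucleotide_profile(
    sites: Sequence[PolyASite],
    genome,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Base frequencies at offsets [-flank, +flank] around poly(A) sites.

    Sequences are taken on the transcribed strand (reverse-complemented for
    minus-strand sites); offset 0 is the cleavage site.  Sites running off a
    chromosome edge contribute only their in-range offsets (denominators
    adjusted); N is excluded from the denominator, so A/C/G/T frequencies
    sum to 1 at every offset with coverage.
    """
    offsets = np.arange(-flank, flank + 1)
    counts = {b: np.zeros(len(offsets), dtype=np.int64) for b in "ACGT"}
    for site in sites:
        length = genome.lengths[site.chrom]
        lo, hi = site.position - flank, site.position + flank + 1
        seq = genome.fetch(site.chrom, lo, hi)
        pad_left = max(0, -lo)
        pad_right = max(0, hi - length)
        seq = "." * pad_left + seq + "." * pad_right
        if site.strand == "-":
            seq = revcomp(seq)  # "." (out-of-range filler) passes through untouched
        for i, base in enumerate(seq):
            if base in counts:
                counts[base][i] += 1
    denom = sum(counts.values()).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = {b: np.where(denom > 0, c / denom, np.nan) for b, c in counts.items()}
    out = pd.DataFrame(freqs, index=pd.Index(offsets, name="offset"))
    out["n"] = denom.astype(int)
    return out


def smooth_lowess(
    x: np.ndarray,
    y: np.ndarray,
    frac: float = DEFAULT_LOWESS_FRAC,
    it: int = DEFAULT_LOWESS_IT,
) -> np.ndarray:
    """Tricube-weighted local linear (lowess) smoothing, same length as x."""
    return _sm_lowess(y, x, frac=frac, it=it, return_sorted=False)


def tss_metagene(
    ua_reads: Mapping[str, Sequence[tuple[PassRead, GeneModel]]],
    totals: Mapping[str, int],
    span: int = DEFAULT_SPAN,
    frac: float = DEFAULT_LOWESS_FRAC,
    it: int = DEFAULT_LOWESS_IT,
) -> pd.DataFrame:
    """Per-base antisense poly(A)-site RPM over [-span, 0) relative to TSS.

    ``ua_reads`` maps sample -> uaRNA-assigned PASS reads paired with their
    host gene; ``totals`` holds per-sample total PASS reads for the RPM
    denominator.  Positions are negative offsets (read poly(A) site upstream
    of TSS); the raw per-base aggregate over all contributing genes is
    reported alongside its lowess smooth.
    """
    if not any(len(v) for v in ua_reads.values()):
        raise ValueError("no uaRNA reads to profile")
    positions = np.arange(-span, 0)
    out = pd.DataFrame({"position": positions})
    for sample, reads in ua_reads.items():
        raw = np.zeros(span)
        for pr, gene in reads:
            d = tss_distance(pr.pa_site, gene)
            if 0 < d <= span:
                raw[span - d] += 1
        raw *= 1e6 / totals[sample]
        out[f"rpm_raw_{sample}"] = raw
        out[f"rpm_smooth_{sample}"] = smooth_lowess(
            positions.astype(float), raw, frac=frac, it=it
        )
    return out
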