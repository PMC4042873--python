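"""Differential uaRNA statistics.

Per gene, all uaRNA reads are pooled and compared to all sense reads of the
gene between two samples with a two-sided Fisher exact test on the 2x2
table ``[[ua_test, sense_test], [ua_ref, sense_ref]]``.  Genes with p below
``alpha`` (default 0.05) are called UP or DN by the direction of the odds
ratio; everything else is NC (not changed).  The global excess of UP over
DN genes is summarized by their ratio and a 1-df chi-squared goodness-of-fit
against a 50:50 split, chi2 = (n_up - n_dn)^2 / (n_up + n_dn), upper-tail p,
no continuity correction.

The two-sided p uses the probability-mass method: the sum of hypergeometric
probabilities, over all tables with the observed margins, that do not exceed
the observed table's probability (with a 1e-7 relative tolerance absorbing
floating-point ties).  No multiple-testing correction enters the UP/DN
calls; a Benjamini-Hochberg column is emitted for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

TIE_REL_TOL = 1e-7

_logfact = gammaln(np.arange(1024) + 1.0)


def _log_factorials(n: int) -> np.ndarray:
    global _logfact
    if n >= len(_logfact):
        _logfact = gammaln(np.arange(max(n + 1, 2 * len(_logfact))) + 1.0)
    return _logfact


@dataclass(frozen=True)
class StatsConfig:
    """Sample roles and thresholds for the differential analysis."""

    test: str
    reference: str
    alpha: float = 0.05
    min_reads_cdf: int = 20
    pseudocount_reads: float = 0.5
    min_reads_call: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_reads_cdf < 0:
            raise ValueError("min_reads_cdf must be >= 0")
        if self.test == self.reference:
            raise ValueError("test and reference samples must differ")


@dataclass(frozen=True)
class DiffResult:
    gene_id: str
    table: tuple[int, int, int, int]  # ua_test, sense_test, ua_ref, sense_ref
    odds_ratio: float
    p: float
    call: str  # UP / DN / NC / low_count


@dataclass(frozen=True)
class EnrichmentSummary:
    n_up: int
    n_dn: int
    ratio: float  # inf when n_dn == 0; nan when nothing called
    chi2: float
    p_chi2: float


def two_sided_pvalues(
    total: int, row1: int, col1: int, tie_rel_tol: float = TIE_REL_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with the given margins.

    Returns (a_values, pvalues) where ``a`` is the top-left cell over its
    support.  Vectorized over the support via a log-factorial table; used by
    :func:`fisher_exact_two_sided` and by margin-sweep validation.
    """
    lf = _log_factorials(total)
    a_lo = max(0, row1 + col1 - total)
    a_hi = min(row1, col1)
    a = np.arange(a_lo, a_hi + 1)
    logpmf = (
        lf[col1] - lf[a] - lf[col1 - a]
        + lf[total - col1] - lf[row1 - a] - lf[total - col1 - row1 + a]
        - (lf[total] - lf[row1] - lf[total - row1])
    )
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + tie_rel_tol), side="right")
    p = np.minimum(csum[idx - 1], 1.0)
    return a, p


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p for the 2x2 table [[a, b], [c, d]].

    Probability-mass method with a 1e-7 relative tie tolerance; p in (0, 1].
    Degenerate margins (an empty row or column pair) give p = 1.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be >= 0")
    total = a + b + c + d
    row1, col1 = a + b, a + c
    if total == 0 or row1 in (0, total) or col1 in (0, total):
        return 1.0
    avals, pvals = two_sided_pvalues(total, row1, col1)
    return float(pvals[a - avals[0]])


def fisher_exact_one_sided_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (upper) Fisher p: evidence that row 1 is enriched in column 1.

    This is the UP-direction tail; unlike the two-sided p it is monotone
    non-increasing as ``a`` grows with b, c, d held fixed.
    """
    total = a + b + c + d
    row1, col1 = a + b, a + c
    if total == 0 or row1 in (0, total) or col1 in (0, total):
        return 1.0
    lf = _log_factorials(total)
    a_lo = max(0, row1 + col1 - total)
    a_hi = min(row1, col1)
    avals = np.arange(a_lo, a_hi + 1)
    logpmf = (
        lf[col1] - lf[avals] - lf[col1 - avals]
        + lf[total - col1] - lf[row1 - avals] - lf[total - col1 - row1 + avals]
        - (lf[total] - lf[row1] - lf[total - row1])
    )
    pmf = np.exp(logpmf)
    return float(min(1.0, pmf[avals >= a].sum()))


def chi_squared_tail(chi2: float) -> float:
    """1-df chi-squared upper-tail probability."""
    return float(chi2_dist.sf(chi2, 1))


def _odds_ratio(ua_t: int, sense_t: int, ua_r: int, sense_r: int) -> float:
    num = ua_t * sense_r
    den = sense_t * ua_r
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def classify_gene(
    gene_id: str, ua_test: int, sense_test: int, ua_ref: int, sense_ref: int,
    cfg: StatsConfig,
) -> DiffResult:
    """Fisher-classify one gene's pooled uaRNA-vs-sense table.

    Genes with zero uaRNA reads in both samples are NC with p = 1 (nothing
    to test).  Any zero cell leaves the odds ratio at 0/inf/nan; the UP/DN
    direction then follows the sign of the cross-product
    ua_test*sense_ref - ua_ref*sense_test, so the call never depends on a
    degenerate ratio.
    """
    table = (ua_test, sense_test, ua_ref, sense_ref)
    if cfg.min_reads_call > 0 and sum(table) < cfg.min_reads_call:
        return DiffResult(gene_id, table, np.nan, np.nan, "low_count")
    if ua_test == 0 and ua_ref == 0:
        return DiffResult(gene_id, table, np.nan, 1.0, "NC")
    p = fisher_exact_two_sided(ua_test, sense_test, ua_ref, sense_ref)
    orat = _odds_ratio(*table)
    direction = ua_test * sense_ref - ua_ref * sense_test
    if p < cfg.alpha and direction > 0:
        call = "UP"
    elif p < cfg.alpha and direction < 0:
        call = "DN"
    else:
        call = "NC"
    return DiffResult(gene_id, table, orat, p, call)


def classify_table(table: pd.DataFrame, cfg: StatsConfig) -> pd.DataFrame:
    """Classify every gene of a count table.

    Expects ``sense_<sample>`` / ``ua_<sample>`` columns for the configured
    test and reference samples; returns a frame indexed by gene_id with the
    2x2 cells, odds ratio, p, BH-adjusted p (reference only) and call.
    """
    for sample in (cfg.test, cfg.reference):
        for cat in ("sense", "ua"):
            if f"{cat}_{sample}" not in table.columns:
                raise ValueError(f"count table lacks column {cat}_{sample}")
    rows = []
    for gene_id, row in table.iterrows():
        r = classify_gene(
            gene_id,
            int(row[f"ua_{cfg.test}"]), int(row[f"sense_{cfg.test}"]),
            int(row[f"ua_{cfg.reference}"]), int(row[f"sense_{cfg.reference}"]),
            cfg,
        )
        rows.append(
            {
                "gene_id": r.gene_id,
                "ua_test": r.table[0], "sense_test": r.table[1],
                "ua_ref": r.table[2], "sense_ref": r.table[3],
                "odds_ratio": r.odds_ratio, "p": r.p, "call": r.call,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    tested = out["p"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def global_enrichment(results: pd.DataFrame | Iterable[DiffResult]) -> EnrichmentSummary:
    """UP:DN ratio with a 1-df goodness-of-fit chi-squared against 50:50."""
    if isinstance(results, pd.DataFrame):
        calls = results["call"]
        n_up = int((calls == "UP").sum())
        n_dn = int((calls == "DN").sum())
    else:
        calls = [r.call for r in results]
        n_up = calls.count("UP")
        n_dn = calls.count("DN")
    n = n_up + n_dn
    if n == 0:
        return EnrichmentSummary(0, 0, np.nan, 0.0, 1.0)
    chi2 = (n_up - n_dn) ** 2 / n
    p = chi_squared_tail(chi2)
    ratio = np.inf if n_dn == 0 else n_up / n_dn
    return EnrichmentSummary(n_up, n_dn, ratio, chi2, p)


def _log2_change(
    table: pd.DataFrame, cat: str, cfg: StatsConfig, totals: Mapping[str, int]
) -> pd.Series:
    pc_t = cfg.pseudocount_reads * 1e6 / totals[cfg.test]
    pc_r = cfg.pseudocount_reads * 1e6 / totals[cfg.reference]
    num = table[f"{cat}_rpm_{cfg.test}"] + pc_t
    den = table[f"{cat}_rpm_{cfg.reference}"] + pc_r
    return np.log2(num / den)


def change_scatter(
    table: pd.DataFrame,
    results: pd.DataFrame,
    cfg: StatsConfig,
    totals: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene log2 uaRNA change vs log2 sense change, flagging p < alpha.

    Changes are log2((rpm_test + pc) / (rpm_ref + pc)) with the pseudocount
    (``pseudocount_reads``, in reads, converted to RPM per sample) keeping
    zero-RPM genes finite.
    """
    out = pd.DataFrame(index=table.index)
    out["log2_ua_change"] = _log2_change(table, "ua", cfg, totals)
    out["log2_sense_change"] = _log2_change(table, "sense", cfg, totals)
    out["significant"] = results["call"].reindex(table.index).isin(["UP", "DN"])
    return out


def _ecdf(values: pd.Series) -> pd.DataFrame:
    v = np.sort(values.to_numpy())
    return pd.DataFrame({"value": v, "cdf": np.arange(1, len(v) + 1) / len(v)})


def cdf_curves(
    table: pd.DataFrame,
    results: pd.DataFrame,
    cfg: StatsConfig,
    totals: Mapping[str, int],
) -> dict[str, pd.DataFrame]:
    """Empirical CDFs of log2 RPM change by transcript category.

    Genes enter a curve only with >= ``min_reads_cdf`` reads of the plotted
    category across the two samples combined.  Categories: uaRNAs; all sense
    transcripts; sense of genes with UP uaRNAs; sense of genes with
    non-regulated (NC, detectable) uaRNAs; sense of genes with no detectable
    uaRNAs.  Empty categories are omitted.
    """
    ua_total = table[f"ua_{cfg.test}"] + table[f"ua_{cfg.reference}"]
    sense_total = table[f"sense_{cfg.test}"] + table[f"sense_{cfg.reference}"]
    ua_ok = ua_total >= cfg.min_reads_cdf
    sense_ok = sense_total >= cfg.min_reads_cdf
    calls = results["call"].reindex(table.index)
    ua_change = _log2_change(table, "ua", cfg, totals)
    sense_change = _log2_change(table, "sense", cfg, totals)

    masks = {
        "uaRNA": (ua_ok, ua_change),
        "sense_all": (sense_ok, sense_change),
        "sense_up_ua": (sense_ok & (calls == "UP"), sense_change),
        "sense_nonreg_ua": (sense_ok & (calls == "NC") & (ua_total > 0), sense_change),
        "sense_no_ua": (sense_ok & (ua_total == 0), sense_change),
    }
    out = {}
    for name, (mask, change) in masks.items():
        vals = change[mask]
        if len(vals) == 0:
            import logging

            logging.getLogger(__name__).warning("CDF category %s is empty; omitted", name)
            continue
        out[name] = _ecdf(vals)
    return out
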