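"""End-to-end orchestration: annotation -> PASS -> assignment -> stats -> profiles.

:func:`run_analysis` drives the whole analysis on in-memory objects and is
the programmatic entry point; :func:`run_pipeline` wraps it with file I/O,
config validation/echo, logging and a manifest, and is what the CLI calls.
Stage order: load annotation, 3' extension, region index, PASS calling,
site clustering, assignment, counting, RPM, per-gene Fisher tests, global
enrichment, profiles.  Re-running with an identical config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    DEFAULT_EXTENSION,
    DEFAULT_UA_WINDOW,
    GeneModel,
    RegionIndex,
    build_region_index,
    extend_three_prime,
    load_gene_models,
    write_bed6,
)
from .assign import (
    Assignment,
    assign_read,
    build_count_table,
    category_tallies,
    rpm_normalize,
)
from .genome import FastaGenome
from .io import (
    read_aligned,
    sites_frame,
    write_pass_bed,
    write_tsv,
)
from .passreads import (
    DEFAULT_CLUSTER_WINDOW,
    DEFAULT_MIN_A_FRACTION,
    DEFAULT_MIN_NONGENOMIC_A,
    PassRead,
    call_pass_library,
    cluster_sites,
    pass_report,
)
from .profiles import (
    DEFAULT_FLANK,
    DEFAULT_LOWESS_FRAC,
    DEFAULT_SPAN,
    nucleotide_profile,
    tss_distance_histogram,
    tss_metagene,
)
from .stats import (
    EnrichmentSummary,
    StatsConfig,
    cdf_curves,
    change_scatter,
    classify_table,
    global_enrichment,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, sample roles, and every stage threshold for one run."""

    genome_fasta: str
    annotation: str
    reads: dict  # sample -> path
    test: str
    reference: str
    out_dir: str
    annotation_format: str = "bed"
    reads_format: str = "auto"
    extension: int = DEFAULT_EXTENSION
    ua_window: int = DEFAULT_UA_WINDOW
    sense_includes_extension: bool = True
    min_nongenomic_a: int = DEFAULT_MIN_NONGENOMIC_A
    min_a_fraction: float = DEFAULT_MIN_A_FRACTION
    cluster_window: int = DEFAULT_CLUSTER_WINDOW
    assignment_mode: str = "pa_site"
    alpha: float = 0.05
    min_reads_cdf: int = 20
    pseudocount_reads: float = 0.5
    hist_bin: int = 100
    flank: int = DEFAULT_FLANK
    metagene_span: int = DEFAULT_SPAN
    lowess_frac: float = DEFAULT_LOWESS_FRAC
    log_level: str = "INFO"


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of issues; empty iff the config is runnable."""
    issues = []
    if not 0 < cfg.alpha < 1:
        issues.append("alpha: must be in (0, 1)")
    if cfg.ua_window <= 0:
        issues.append("ua_window: must be > 0")
    if cfg.extension < 0:
        issues.append("extension: must be >= 0")
    if cfg.min_nongenomic_a < 0:
        issues.append("min_nongenomic_a: must be >= 0")
    if not 0 <= cfg.min_a_fraction <= 1:
        issues.append("min_a_fraction: must be in [0, 1]")
    if cfg.cluster_window < 0:
        issues.append("cluster_window: must be >= 0")
    if cfg.min_reads_cdf < 0:
        issues.append("min_reads_cdf: must be >= 0")
    if cfg.assignment_mode not in ("pa_site", "any_overlap"):
        issues.append("assignment_mode: must be 'pa_site' or 'any_overlap'")
    if cfg.test == cfg.reference:
        issues.append("test/reference: sample roles must differ")
    if cfg.test not in cfg.reads:
        issues.append(f"reads: missing test sample {cfg.test!r}")
    if cfg.reference not in cfg.reads:
        issues.append(f"reads: missing reference sample {cfg.reference!r}")
    for sample, path in cfg.reads.items():
        if not Path(path).exists():
            issues.append(f"reads[{sample}]: no such file {path}")
    if not Path(cfg.genome_fasta).exists():
        issues.append(f"genome_fasta: no such file {cfg.genome_fasta}")
    if not Path(cfg.annotation).exists():
        issues.append(f"annotation: no such file {cfg.annotation}")
    return issues


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, in memory."""

    genes: list[GeneModel]
    index: RegionIndex
    pass_reads: dict            # sample -> list[PassRead]
    input_counts: dict          # sample -> int
    totals: dict                # sample -> total PASS reads
    report: pd.DataFrame
    sites: list
    assignments: dict           # sample -> list[Assignment]
    tallies: dict               # sample -> category -> count
    count_table: pd.DataFrame   # counts + RPM
    results: pd.DataFrame       # per-gene Fisher outcomes
    enrichment: EnrichmentSummary
    tss_hist: pd.DataFrame
    nt_profile: pd.DataFrame
    metagene: pd.DataFrame | None
    scatter: pd.DataFrame
    cdfs: dict


def run_analysis(
    genome,
    genes: Sequence[GeneModel],
    reads_by_sample: Mapping[str, Sequence],
    test: str,
    reference: str,
    *,
    extension: int = DEFAULT_EXTENSION,
    ua_window: int = DEFAULT_UA_WINDOW,
    sense_includes_extension: bool = True,
    min_nongenomic_a: int = DEFAULT_MIN_NONGENOMIC_A,
    min_a_fraction: float = DEFAULT_MIN_A_FRACTION,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    assignment_mode: str = "pa_site",
    alpha: float = 0.05,
    min_reads_cdf: int = 20,
    pseudocount_reads: float = 0.5,
    hist_bin: int = 100,
    flank: int = DEFAULT_FLANK,
    metagene_span: int = DEFAULT_SPAN,
    lowess_frac: float = DEFAULT_LOWESS_FRAC,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs and return every product."""
    samples = list(reads_by_sample)
    for role, name in (("test", test), ("reference", reference)):
        if name not in samples:
            raise PipelineError("setup", f"{role} sample {name!r} not among read sets")

    lengths = genome.lengths
    genes = extend_three_prime(list(genes), lengths, extension)
    index = build_region_index(
        genes, lengths, ua_window, sense_includes_extension=sense_includes_extension
    )

    pass_reads: dict[str, list[PassRead]] = {}
    input_counts: dict[str, int] = {}
    spans_by_sample: dict[str, dict] = {}
    for sample in samples:
        reads = reads_by_sample[sample]
        prs, n_in = call_pass_library(reads, genome, min_nongenomic_a, min_a_fraction)
        pass_reads[sample] = prs
        input_counts[sample] = n_in
        if assignment_mode == "any_overlap":
            spans_by_sample[sample] = {r.read_id: (r.aln_start, r.aln_end) for r in reads}
    totals = {s: len(pass_reads[s]) for s in samples}
    report = pass_report(input_counts, totals)

    sites = cluster_sites(pass_reads, cluster_window)

    assignments: dict[str, list[Assignment]] = {}
    ua_reads_by_sample: dict[str, list] = {}
    for sample in samples:
        spans = spans_by_sample.get(sample)
        asn, ua_pairs = [], []
        for pr in pass_reads[sample]:
            span = spans.get(pr.read_id) if spans is not None else None
            a = assign_read(pr, index, aln_span=span)
            asn.append(a)
            if a.category == "uaRNA":
                ua_pairs.append((pr, index.genes[a.gene_id]))
        assignments[sample] = asn
        ua_reads_by_sample[sample] = ua_pairs
    tallies = {s: category_tallies(assignments[s]) for s in samples}

    table = build_count_table(assignments, [g.gene_id for g in genes])
    table = rpm_normalize(table, totals)

    stats_cfg = StatsConfig(
        test=test, reference=reference, alpha=alpha,
        min_reads_cdf=min_reads_cdf, pseudocount_reads=pseudocount_reads,
    )
    results = classify_table(table, stats_cfg)
    enrichment = global_enrichment(results)

    # uaRNA-assigned poly(A) sites anchor the descriptive profiles
    ua_site_pairs = []
    for site in sites:
        probe = PassRead("site", site.chrom, site.strand, site.position, 0)
        a = assign_read(probe, index)
        if a.category == "uaRNA":
            ua_site_pairs.append((site, index.genes[a.gene_id]))
    tss_hist = tss_distance_histogram(ua_site_pairs, max_dist=ua_window, bin_size=hist_bin)
    ua_sites = [s for s, _ in ua_site_pairs]
    nt_profile = nucleotide_profile(ua_sites, genome, flank=flank)
    if any(len(v) for v in ua_reads_by_sample.values()):
        metagene = tss_metagene(
            ua_reads_by_sample, totals, span=metagene_span, frac=lowess_frac
        )
    else:
        logger.warning("no uaRNA reads in any sample; metagene skipped")
        metagene = None

    scatter = change_scatter(table, results, stats_cfg, totals)
    cdfs = cdf_curves(table, results, stats_cfg, totals)

    return AnalysisResult(
        genes=genes, index=index, pass_reads=pass_reads, input_counts=input_counts,
        totals=totals, report=report, sites=sites, assignments=assignments,
        tallies=tallies, count_table=table, results=results, enrichment=enrichment,
        tss_hist=tss_hist, nt_profile=nt_profile, metagene=metagene,
        scatter=scatter, cdfs=cdfs,
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tag every failure
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based end-to-end run; writes outputs + manifest, returns the report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    issues = validate_config(cfg)
    if issues:
        raise PipelineError("config", "; ".join(issues))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = _stage("load_genome")(FastaGenome)(cfg.genome_fasta)
    with open(cfg.annotation) as fh:
        genes = _stage("load_annotation")(load_gene_models)(
            fh, genome.lengths, cfg.annotation_format
        )
    reads_by_sample = {
        sample: _stage("load_reads")(read_aligned)(path, cfg.reads_format)
        for sample, path in cfg.reads.items()
    }

    res = _stage("analysis")(run_analysis)(
        genome, genes, reads_by_sample, cfg.test, cfg.reference,
        extension=cfg.extension, ua_window=cfg.ua_window,
        sense_includes_extension=cfg.sense_includes_extension,
        min_nongenomic_a=cfg.min_nongenomic_a, min_a_fraction=cfg.min_a_fraction,
        cluster_window=cfg.cluster_window, assignment_mode=cfg.assignment_mode,
        alpha=cfg.alpha, min_reads_cdf=cfg.min_reads_cdf,
        pseudocount_reads=cfg.pseudocount_reads, hist_bin=cfg.hist_bin,
        flank=cfg.flank, metagene_span=cfg.metagene_span, lowess_frac=cfg.lowess_frac,
    )

    files = _write_outputs(out, cfg, res)
    report = _run_report(cfg, res)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "uarna_version": __version__,
        "config": dataclasses.asdict(cfg),
        "files": sorted(files + ["summary.json"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write_outputs(out: Path, cfg: RunConfig, res: AnalysisResult) -> list[str]:
    files = []

    def _add(name):
        files.append(name)
        return out / name

    write_bed6(_add("sense_regions.bed"), res.index.sense_regions())
    write_bed6(_add("ua_windows.bed"), res.index.ua_regions())
    for sample in res.pass_reads:
        write_pass_bed(_add(f"pass_reads_{sample}.bed"), res.pass_reads[sample])
    write_tsv(_add("pass_report.tsv"), res.report, index=False)
    write_tsv(_add("polya_sites.tsv"), sites_frame(res.sites, list(res.pass_reads)),
              index=False)
    write_tsv(_add("counts.tsv"), res.count_table)
    write_tsv(_add("diff_results.tsv"), res.results)
    write_tsv(_add("tss_distance_hist.tsv"), res.tss_hist, index=False)
    write_tsv(_add("nucleotide_profile.tsv"), res.nt_profile)
    if res.metagene is not None:
        write_tsv(_add("tss_metagene.tsv"), res.metagene, index=False)
    write_tsv(_add("change_scatter.tsv"), res.scatter)
    for name, frame in res.cdfs.items():
        write_tsv(_add(f"cdf_{name}.tsv"), frame, index=False)
    return files


def _run_report(cfg: RunConfig, res: AnalysisResult) -> dict:
    enr = res.enrichment
    return {
        "samples": {
            s: {
                "input_reads": res.input_counts[s],
                "pass_reads": res.totals[s],
                "assigned": res.tallies[s],
            }
            for s in res.pass_reads
        },
        "n_genes": len(res.genes),
        "n_polya_sites": len(res.sites),
        "enrichment": {
            "n_up": enr.n_up,
            "n_dn": enr.n_dn,
            "ratio": None if pd.isna(enr.ratio) else (
                "inf" if enr.ratio == float("inf") else enr.ratio
            ),
            "chi2": enr.chi2,
            "p_chi2": enr.p_chi2,
        },
        "test": cfg.test,
        "reference": cfg.reference,
    }
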