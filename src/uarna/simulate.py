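"""Seeded generator of toy 3'-end-sequencing datasets with truth labels.

The generator emulates the statistical structure the analysis assumes: a
uniform-base genome; non-overlapping protein-coding genes; strand-specific
3'-end reads whose poly(A) sites concentrate at gene 3' ends (sense) and
within 2 kb upstream of TSSs on the antisense strand (uaRNA); two-condition
count data with optional planted genes whose uaRNA:sense ratio rises (UP)
or falls (DN) by a configured fold.  PASS-destined reads carry a purely
adenosine tail; non-PASS reads carry a templated, single-A or empty tail.
Every read is consistent with the emitted genome, and a truth table records
each read's class and each gene's regulation class and expected counts.

Default conditions are desk-scale: 2e5 reads per library (the sequenced
libraries the model emulates ran ~4 million), 1000 genes, Poisson counts.
When ``p_templated_context`` is 0 (default) the generator rewrites the
bases immediately downstream of every designated cleavage position to
non-A, so tails are unambiguous and truth labels match the PASS rule
exactly; raising it plants templated-A context that exercises the
longest-templated-prefix logic.

All randomness flows through one ``numpy.random.Generator`` (PCG64), so a
seed fixes the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .genome import DictGenome, revcomp
from .passreads import AlignedRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_A = "CGT"


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions emulated."""

    seed: int = 0
    # genome / annotation geometry
    n_chroms: int = 4
    chrom_len: int = 4_000_000
    n_genes: int = 1000
    gene_len_min: int = 2000
    gene_len_max: int = 8000
    min_gap: int = 7000
    # expression model
    log_expr_sd: float = 0.75
    ua_ratio: float = 0.08          # baseline uaRNA:sense expression, detectable genes
    frac_ua_genes: float = 0.3      # fraction of genes with detectable uaRNA
    n_up: int = 0                   # planted genes with uaRNA fold-up in test
    n_dn: int = 0                   # planted genes with uaRNA fold-down in test
    fold: float = 4.0
    # sampling
    reads_per_library: int = 200_000
    noise_model: str = "poisson"    # "poisson" | "nb"
    nb_dispersion: float = 0.1
    samples: tuple[str, str] = ("mut", "ctrl")  # (test, reference)
    # read / tail model
    read_len: int = 50
    tail_len_min: int = 4
    tail_len_max: int = 12
    frac_non_pass: float = 0.15
    frac_noise: float = 0.02        # background reads at random positions
    n_noise_sites: int = 200
    p_templated_context: float = 0.0
    plant_motif: str | None = None  # e.g. "AATAAA"
    motif_offset: int = -25         # start of motif relative to cleavage site
    max_sense_sites: int = 3
    max_ua_sites: int = 2

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValueError("n_genes and n_chroms must be > 0")
        if not 0 < self.gene_len_min <= self.gene_len_max:
            raise ValueError("bad gene length range")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        for name in ("frac_ua_genes", "frac_non_pass", "frac_noise", "p_templated_context"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.ua_ratio < 1:
            raise ValueError("ua_ratio must be in (0, 1)")
        if self.n_up + self.n_dn > int(round(self.frac_ua_genes * self.n_genes)):
            raise ValueError("planted genes exceed the detectable-uaRNA pool")
        if self.noise_model not in ("poisson", "nb"):
            raise ValueError("noise_model must be 'poisson' or 'nb'")

    @property
    def test_sample(self) -> str:
        return self.samples[0]

    @property
    def reference_sample(self) -> str:
        return self.samples[1]


@dataclass
class TruthTable:
    """Per-read and per-gene ground truth, exactly consistent with output."""

    reads: pd.DataFrame   # library, read_id, category, gene_id, pass_destined, pa_site
    genes: pd.DataFrame   # gene_id, ua_class, expected_{sense,ua}_{sample}


@dataclass
class _Site:
    chrom: str
    strand: str
    pos: int
    category: str          # sense / uaRNA / noise
    gene_id: str | None
    weight: dict           # sample -> expected relative expression


@dataclass
class SimData:
    cfg: SimConfig
    genome: DictGenome
    genes: list[GeneModel]
    libraries: dict[str, list[AlignedRead]]
    truth: TruthTable


def simulate_genome(cfg: SimConfig, rng: np.random.Generator) -> DictGenome:
    """I.i.d. uniform-base genome; motif planting happens at read time."""
    cfg.validate()
    seqs = {}
    for i in range(cfg.n_chroms):
        idx = rng.integers(0, 4, cfg.chrom_len)
        seqs[f"chr{i + 1}"] = _BASES[idx].tobytes()
    return DictGenome(seqs)


def simulate_annotation(
    cfg: SimConfig, genome: DictGenome, rng: np.random.Generator
) -> list[GeneModel]:
    """Non-overlapping genes with >= ``min_gap`` between neighbours.

    Genes are spread evenly over chromosomes; within each chromosome, gaps
    are a random integer composition of the slack beyond the minimum gap.
    Raises when the requested genes plus gaps cannot fit.
    """
    chroms = genome.chroms()
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    serial = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        length = genome.lengths[chrom]
        lens = rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1, n)
        slack = length - int(lens.sum()) - (n + 1) * cfg.min_gap
        if slack < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: {n} genes need "
                f"{int(lens.sum()) + (n + 1) * cfg.min_gap} bp > {length} bp"
            )
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for j in range(n):
            pos += cfg.min_gap + int(extra[j])
            start = pos
            end = start + int(lens[j])
            pos = end
            serial += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(gene_id=f"g{serial:05d}", chrom=chrom, strand=strand,
                          start=start, end=end)
            )
    return genes


def write_bed12(path, genes: Iterable[GeneModel]) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "w") as fh:
        for g in genes:
            size = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{size},\t0,\n"
            )


def _transcript_step(strand: str) -> int:
    return 1 if strand == "+" else -1


def _write_transcribed(genome: DictGenome, chrom: str, strand: str, pos: int, base: str):
    """Write ``base`` as read on the transcribed strand at genomic ``pos``."""
    length = genome.lengths[chrom]
    if not 0 <= pos < length:
        return
    genome.write_base(chrom, pos, base if strand == "+" else revcomp(base))


def _prepare_site_context(
    genome: DictGenome, site: _Site, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """Rewrite downstream cleavage context and plant the poly(A) signal.

    Downstream (transcript direction) of the cleavage site, the first
    ``tail_len_max`` bases become non-A unless templated-A context is
    requested, in which case 1-3 As are written first.  The motif, when
    configured, is written upstream at ``motif_offset`` for sense and uaRNA
    sites.
    """
    step = _transcript_step(site.strand)
    n_a = 0
    if cfg.p_templated_context > 0 and rng.random() < cfg.p_templated_context:
        n_a = int(rng.integers(1, 4))
    for i in range(cfg.tail_len_max):
        p = site.pos + (i + 1) * step
        base = "A" if i < n_a else _NON_A[rng.integers(0, 3)]
        _write_transcribed(genome, site.chrom, site.strand, p, base)
    if cfg.plant_motif and site.category != "noise":
        for i, base in enumerate(cfg.plant_motif):
            p = site.pos + (cfg.motif_offset + i) * step
            _write_transcribed(genome, site.chrom, site.strand, p, base)


def _design_sites(
    cfg: SimConfig,
    genes: list[GeneModel],
    genome: DictGenome,
    rng: np.random.Generator,
) -> tuple[list[_Site], pd.DataFrame]:
    """Choose poly(A) sites and per-sample expected expression weights."""
    test, ref = cfg.samples
    n = len(genes)
    lam = rng.lognormal(0.0, cfg.log_expr_sd, n)
    n_ua = int(round(cfg.frac_ua_genes * n))
    perm = rng.permutation(n)
    ua_class = np.full(n, "none", dtype=object)
    ua_class[perm[: cfg.n_up]] = "UP"
    ua_class[perm[cfg.n_up : cfg.n_up + cfg.n_dn]] = "DN"
    ua_class[perm[cfg.n_up + cfg.n_dn : n_ua]] = "null"

    sites: list[_Site] = []
    gene_rows = []
    for i, g in enumerate(genes):
        step = _transcript_step(g.strand)
        three_prime = g.end - 1 if g.strand == "+" else g.start
        # sense poly(A) sites near the native 3' end, primary at the terminus
        k = int(rng.integers(1, cfg.max_sense_sites + 1))
        offsets = [0] + sorted(set(rng.integers(60, 300, k - 1).tolist()))
        w = rng.dirichlet(np.ones(len(offsets)))
        for off, wt in zip(offsets, w):
            pos = three_prime - off * step
            sites.append(
                _Site(g.chrom, g.strand, int(pos), "sense", g.gene_id,
                      {test: lam[i] * wt, ref: lam[i] * wt})
            )
        # uaRNA sites within the 2 kb antisense window upstream of the TSS
        ua_t = ua_r = 0.0
        if ua_class[i] != "none":
            base = cfg.ua_ratio * lam[i]
            ua_r = base
            ua_t = base * cfg.fold if ua_class[i] == "UP" else (
                base / cfg.fold if ua_class[i] == "DN" else base
            )
            m = int(rng.integers(1, cfg.max_ua_sites + 1))
            dists = sorted(set(rng.integers(1, 2001, m).tolist()))
            wua = rng.dirichlet(np.ones(len(dists)))
            anti = "-" if g.strand == "+" else "+"
            for d, wt in zip(dists, wua):
                pos = g.tss - d * step
                sites.append(
                    _Site(g.chrom, anti, int(pos), "uaRNA", g.gene_id,
                          {test: ua_t * wt, ref: ua_r * wt})
                )
        gene_rows.append(
            {"gene_id": g.gene_id, "ua_class": ua_class[i], "lam": lam[i],
             f"expr_sense_{test}": lam[i], f"expr_sense_{ref}": lam[i],
             f"expr_ua_{test}": ua_t, f"expr_ua_{ref}": ua_r}
        )

    # background noise sites anywhere on the genome
    signal = sum(s.weight[test] for s in sites)
    if cfg.frac_noise > 0 and cfg.n_noise_sites > 0:
        w_noise = cfg.frac_noise / (1 - cfg.frac_noise) * signal / cfg.n_noise_sites
        margin = cfg.read_len + cfg.tail_len_max + 1
        chroms = genome.chroms()
        for _ in range(cfg.n_noise_sites):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(margin, genome.lengths[chrom] - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append(_Site(chrom, strand, pos, "noise", None,
                               {test: w_noise, ref: w_noise}))
    return sites, pd.DataFrame(gene_rows)


def _draw_count(mu: float, cfg: SimConfig, rng: np.random.Generator) -> int:
    if mu <= 0:
        return 0
    if cfg.noise_model == "poisson":
        return int(rng.poisson(mu))
    shape = 1.0 / cfg.nb_dispersion
    return int(rng.poisson(rng.gamma(shape, mu / shape)))


def simulate_reads(
    cfg: SimConfig,
    genome: DictGenome,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[dict[str, list[AlignedRead]], TruthTable]:
    """Draw two libraries of aligned reads plus their truth table.

    Mutates ``genome`` in place (cleavage context, optional motif) before
    any read is drawn, so emitted alignments always match the emitted
    sequence.
    """
    cfg.validate()
    sites, gene_truth = _design_sites(cfg, genes, genome, rng)
    for site in sites:
        _prepare_site_context(genome, site, cfg, rng)

    samples = list(cfg.samples)
    totals = {s: sum(site.weight[s] for site in sites) for s in samples}
    libraries: dict[str, list[AlignedRead]] = {s: [] for s in samples}
    truth_rows = []
    expected = {s: {} for s in samples}  # (gene, category) -> expected count

    for sample in samples:
        scale = cfg.reads_per_library / totals[sample]
        serial = 0
        for site in sites:
            mu = site.weight[sample] * scale
            if site.gene_id is not None:
                key = (site.gene_id, site.category)
                expected[sample][key] = expected[sample].get(key, 0.0) + mu
            count = _draw_count(mu, cfg, rng)
            if count == 0:
                continue
            length = genome.lengths[site.chrom]
            for _ in range(count):
                serial += 1
                read_id = f"{sample}.{serial:07d}"
                tail_len = int(rng.integers(cfg.tail_len_min, cfg.tail_len_max + 1))
                pass_destined = rng.random() >= cfg.frac_non_pass
                if site.strand == "+":
                    aln_start = max(0, site.pos - cfg.read_len + 1)
                    aln_end = site.pos + 1
                else:
                    aln_start = site.pos
                    aln_end = min(length, site.pos + cfg.read_len)
                if pass_destined:
                    tail = "A" * tail_len
                else:
                    u = rng.random()
                    if u < 0.6:  # fully templated continuation
                        if site.strand == "+":
                            tail = genome.fetch(site.chrom, aln_end, aln_end + tail_len)
                        else:
                            tail = revcomp(
                                genome.fetch(site.chrom, aln_start - tail_len, aln_start)
                            )
                    elif u < 0.9:  # a single A: too few non-genomic As
                        tail = "A"
                    else:
                        tail = ""
                libraries[sample].append(
                    AlignedRead(read_id, site.chrom, site.strand, aln_start, aln_end, tail)
                )
                truth_rows.append(
                    {"library": sample, "read_id": read_id, "category": site.category,
                     "gene_id": site.gene_id, "pass_destined": pass_destined,
                     "pa_site": site.pos}
                )

    reads_truth = pd.DataFrame(
        truth_rows,
        columns=["library", "read_id", "category", "gene_id", "pass_destined", "pa_site"],
    )
    for sample in samples:
        for cat, col in (("sense", f"expected_sense_{sample}"),
                         ("uaRNA", f"expected_ua_{sample}")):
            scale_map = expected[sample]
            gene_truth[col] = [
                scale_map.get((g, cat), 0.0) for g in gene_truth["gene_id"]
            ]
    return libraries, TruthTable(reads=reads_truth, genes=gene_truth)


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Genome + annotation + reads + truth under one seeded generator."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    genome = simulate_genome(cfg, rng)
    genes = simulate_annotation(cfg, genome, rng)
    libraries, truth = simulate_reads(cfg, genome, genes, rng)
    return SimData(cfg=cfg, genome=genome, genes=genes, libraries=libraries, truth=truth)


def mirror_dataset(
    genome: DictGenome,
    genes: list[GeneModel],
    libraries: dict[str, list[AlignedRead]],
) -> tuple[DictGenome, list[GeneModel], dict[str, list[AlignedRead]]]:
    """Reverse-complement the whole dataset (strand-mirror transform).

    Every chromosome is reverse-complemented, every feature's strand is
    flipped and its coordinates mirrored (x -> L - x on interval bounds).
    Gene extensions are reset to native spans (they are re-derived by the
    pipeline).  The analysis is invariant under this transform.
    """
    lengths = genome.lengths
    g2 = DictGenome({c: revcomp(genome.fetch(c, 0, lengths[c])) for c in genome.chroms()})
    flip = {"+": "-", "-": "+"}
    genes2 = [
        GeneModel(gene_id=g.gene_id, chrom=g.chrom, strand=flip[g.strand],
                  start=lengths[g.chrom] - g.end, end=lengths[g.chrom] - g.start)
        for g in genes
    ]
    genes2.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    libs2 = {
        s: [
            AlignedRead(r.read_id, r.chrom, flip[r.strand],
                        lengths[r.chrom] - r.aln_end, lengths[r.chrom] - r.aln_start,
                        r.tail_seq)
            for r in reads
        ]
        for s, reads in libraries.items()
    }
    return g2, genes2, libs2
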