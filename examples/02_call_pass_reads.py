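"""Call poly(A)-site-supporting (PASS) reads and cluster poly(A) sites.

A read is PASS when its 3' soft-clipped tail carries at least two
adenosines that the reference does not template (the longest templated
prefix is stripped first).  The per-library report mirrors the tallies a
3'-end-seq study reports per sequencing library.
"""

from uarna import (
    AlignedRead,
    DictGenome,
    SimConfig,
    call_pass,
    call_pass_library,
    cluster_sites,
    pass_report,
    simulate_dataset,
)

# hand-worked example: the reference continues "GCTA", so all four tail As
# are non-genomic -> PASS with poly(A) site at the last aligned base (149)
genome = DictGenome({"chr1": "C" * 150 + "GCTA" + "C" * 46})
read = AlignedRead("demo", "chr1", "+", 100, 150, "AAAA")
print("hand-worked call:", call_pass(read, genome))

# whole-library calling on a simulated dataset
sim = simulate_dataset(SimConfig(seed=7, n_chroms=1, chrom_len=1_600_000,
                                 n_genes=120, reads_per_library=30_000))
pass_by_lib, inputs = {}, {}
for lib, reads in sim.libraries.items():
    pass_by_lib[lib], inputs[lib] = call_pass_library(reads, sim.genome)

report = pass_report(inputs, {s: len(p) for s, p in pass_by_lib.items()})
print("\nper-library PASS report:")
print(report.to_string(index=False))

sites = cluster_sites(pass_by_lib, window=24)
print(f"\nclustered poly(A) sites: {len(sites)} "
      f"(total reads conserved: {sum(s.total for s in sites)})")
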