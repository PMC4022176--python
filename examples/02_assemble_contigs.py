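"""De novo unitig assembly with an exhaustive k-mer sweep.

Simulates error-bearing reads from a small diploid genome, sweeps k and
keeps the assembly with the longest N50 (ties to the larger k). Note how
heterozygous sites bound contig length: without bubble popping, every
het site branches the graph.
"""

from refscaff import assemble, simulate
from refscaff.reads import LibrarySpec

ref = simulate.generate_reference(1, [150_000], 0.42, seed=7)
haps, het = simulate.make_diploid(ref, het_rate=0.001, seed=8)
spec = LibrarySpec(kind="single_end", read_length=75, coverage=30,
                   error_rate=0.001, name="se")
reads = simulate.simulate_reads(haps, spec, seed=9)

result = assemble.select_k(reads.batches[0], k_min=21, k_max=41, k_step=2)
print(result.stats[["k", "n_contigs", "total_length", "n50",
                    "max_length"]].to_string(index=False))
stats = assemble.AssemblyStats.from_contigs(result.contigs)
print(f"\nbest k = {result.best_k}: {stats.n_contigs} contigs, "
      f"N50 {stats.n50} bp, mean depth {stats.depth_mean:.1f}")
print(f"planted het sites: {len(het['scaffold_1'])} "
      "(each one is a potential contig break)")
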