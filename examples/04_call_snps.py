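"""Heterozygous SNP calling inside a coverage window, scored vs truth.

Maps reads from a diploid individual back to its genome, calls SNPs with
the diallelic genotype-likelihood model in a mean-relative coverage
window (the scaled analogue of absolute 50-100X cutoffs), and reports
precision/recall against the planted sites plus the Ts/Tv ratio.
"""

from refscaff import align, simulate, variants
from refscaff.reads import LibrarySpec

ref = simulate.generate_reference(1, [200_000], 0.42, seed=21)
haps, het_truth = simulate.make_diploid(ref, het_rate=0.001, seed=22)

index = align.SeqIndex(ref, 13)
counts = align.new_pileup(ref)
for cov, seed in ((30, 23), (30, 24)):   # two libraries, 60X aggregate
    spec = LibrarySpec(kind="single_end", read_length=75, coverage=cov,
                       error_rate=0.001, name=f"lib{seed}")
    reads = simulate.simulate_reads(haps, spec, seed=seed)
    aln = align.map_reads(reads.batches[0], index, align.read_preset())
    align.add_read_alignments(counts, aln)

config = variants.CallingConfig(cov_min=0.85, cov_max=1.75,
                                mean_relative=True, base_error=0.01)
result = variants.call_snps(counts, ref, config)
het_calls = [s for s in result.snps if s.genotype == variants.HET]
truth = set(het_truth["scaffold_1"]["position"].tolist())
tp = sum(1 for s in het_calls if (s.position - 1) in truth)

print(f"mean depth: {result.mean_depth:.1f}X; "
      f"window {config.window(result.mean_depth)[0]:.0f}-"
      f"{config.window(result.mean_depth)[1]:.0f}X")
print(f"planted het sites: {len(truth)}; called: {len(het_calls)}")
print(f"precision: {tp / len(het_calls):.3f}  recall: {tp / len(truth):.3f}")
ratio = variants.tstv(het_calls)
print(f"Ts/Tv: {ratio.ratio:.2f} ({ratio.transitions} transitions, "
      f"{ratio.transversions} transversions; planted bias 2:1)")
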