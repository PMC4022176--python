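"""Reference-guided backbone: map contigs + mate pairs, take consensus,
fill gaps.

The draft lives on the reference coordinate frame: scaffold lengths
match the reference exactly, with N where evidence is missing. Gap
filling can only turn N into bases, never the reverse.
"""

from refscaff import align, assemble, scaffold, simulate
from refscaff.reads import LibrarySpec

ref = simulate.generate_reference(1, [200_000], 0.42, seed=11,
                                  names=["chr1"])
focal, truth = simulate.evolve_genome(ref, 0.02, 2e-4, seed=12)
haps, _het = simulate.make_diploid(focal, 0.001, seed=13)

mp = LibrarySpec(kind="mate_pair", read_length=60, coverage=40,
                 insert_mean=2000, insert_sd=200, error_rate=0.001,
                 name="mp2k")
reads = simulate.simulate_reads(haps, mp, seed=14)
contigs = assemble.build_contigs(
    simulate.simulate_reads(haps, LibrarySpec(
        kind="single_end", read_length=75, coverage=20, error_rate=0.001,
        name="se"), seed=15).batches[0], k=31)

read_index = align.SeqIndex(ref, 13)
a1, a2, est = align.align_pairs((reads.batches[0], reads.batches[1]),
                                read_index, align.read_preset())
print(f"insert estimate: {est.mean:.0f} +/- {est.sd:.0f} "
      f"(from {est.n_used} unique pairs)")

contig_index = align.SeqIndex(ref, 15)
records, queries = [], {}
for contig in contigs:
    if len(contig) < 1000:
        continue
    recs = align.align_long(contig, contig_index, align.contig_preset())
    if recs and recs[0].mapq_proxy == align.UNIQUE:
        records.append(recs[0])
        queries[contig.id] = contig
print(f"contigs >= 1 kb mapped uniquely: {len(records)}")

evidence = scaffold.merge_evidence(records, queries, [a1, a2], ref)
masks, depth = align.coverage_filter(evidence)
backbone = scaffold.consensus(evidence, ref, coverage_mask=masks)
gf = scaffold.gap_fill(backbone, contigs)
draft = gf.scaffolds[0]
print(f"mean evidence depth: {depth:.1f}")
print(f"backbone non-N: {backbone[0].non_n()} / {len(draft)} bp")
print(f"final    non-N: {draft.non_n()} / {len(draft)} bp "
      f"(+{gf.filled_positions['chr1']} filled, never fewer)")
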