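"""Homology annotation: reciprocal best hits and CDS coverage.

Searches gene sequences against a draft with gaps, keeps mutual best
hits below the e-value cutoff, and measures what fraction of each
gene's coding intervals the draft actually covers (the 'U'-shaped
completeness picture: genes tend to be nearly fully covered or barely).
"""

import numpy as np

from refscaff import compare, seqcodec, simulate
from refscaff.genome import Genome
from refscaff.pipeline import gene_span_sequences

ref = simulate.generate_reference(1, [150_000], 0.42, seed=41,
                                  names=["chr1"])
genes = simulate.random_gene_models(ref, 15, seed=42)

# a draft with N blocks knocked into it (as gap filling leaves behind)
rng = np.random.default_rng(43)
codes = ref.codes("chr1").copy()
for start in rng.integers(0, 140_000, size=12):
    codes[start:start + int(rng.integers(500, 4000))] = seqcodec.N
draft = Genome([("chr1", seqcodec.decode(codes))])

gene_seqs = gene_span_sequences(genes, ref)
fwd = compare.search_hits(gene_seqs, draft)
gene_db = Genome(list(gene_seqs.items()))
region_seqs = {}
for _, row in (fwd.sort_values(["query", "evalue"])
               .drop_duplicates("query").iterrows()):
    seg = draft.codes(row["scaffold"])[row["start"]:row["end"]]
    region_seqs[row["subject"]] = seqcodec.decode(seg)
rev = compare.search_hits(region_seqs, gene_db)
rev = rev.assign(subject=rev["scaffold"])  # subject column = the gene id
pairs = compare.reciprocal_best_hits(fwd, rev, evalue_cutoff=1e-10)
print(f"genes: {len(genes)}; reciprocal best hits: {len(pairs)}")

table, hist, over_90 = compare.cds_coverage(genes, draft)
print(f"CDS coverage histogram (10% bins): {hist.tolist()}")
print(f"genes with >90% of coding sequence covered: {over_90}")
print(table[["gene_id", "cds_length", "covered",
             "fraction"]].to_string(index=False,
                                    float_format=lambda x: f"{x:.2f}"))
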