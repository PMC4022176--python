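"""Generate a small synthetic study fixture and inspect its truth.

Builds an ancestral reference (two autosomes + a Z-classed scaffold),
evolves a focal genome from it, plants heterozygous sites, and simulates
the three sequencing libraries. Every planted difference is recorded, so
downstream estimates can be scored against ground truth.
"""

from refscaff.config import SimulationConfig
from refscaff.pipeline import simulate_inputs

config = SimulationConfig(scaffold_lengths=[120_000, 80_000, 60_000],
                          divergent_segment_start=30_000,
                          divergent_segment_length=20_000,
                          n_genes=10)
inputs = simulate_inputs(config, seed=1)

print("reference scaffolds:", inputs.reference.lengths)
print("chromosome classes: ", inputs.reference.chrom_class_map)
subs = sum(len(df) for df in inputs.truth.substitutions.values())
hets = sum(len(df) for df in inputs.het_truth.values())
print(f"planted substitutions: {subs}  (2% background, 25% island, 1.5x Z)")
print(f"planted indel events:  {len(inputs.truth.indel_events)}")
print(f"planted het sites:     {hets}  (~0.1% of the genome)")
print(f"single-end reads:      {inputs.se_reads.n}  (75 bp, 20X)")
for m1, _m2 in inputs.mp_libraries:
    print(f"mate pairs ({m1.library.name}):   {m1.n}  "
          f"(60x60 bp, insert {m1.library.insert_mean})")
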