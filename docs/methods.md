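# Methods

`refscaff` implements, at desk scale, a reference-guided whole-genome
assembly workflow for a non-model organism sequenced with short reads
(the classic galliform setting: a grouse-like focal species projected
onto a chicken-like reference): short
reads are first assembled de novo into contigs, then both the long
contigs and the mate-pair reads are mapped onto the genome of a related,
well-assembled species; the merged alignments yield a consensus "draft"
genome expressed in the reference's coordinate frame, which is then
mined for heterozygous SNPs and screened for fast-evolving regions.
This note records the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Pipeline model

The draft genome is a *projection*: each draft scaffold has exactly the
length of the reference scaffold it mirrors, with `N` wherever no
evidence places a base. This deliberately reproduces the central
trade-off of the approach — rearrangements and reference-absent sequence
cannot be represented on the backbone (unplaced contigs partially
compensate), and at heterozygous or cross-species-ambiguous columns the
consensus is biased toward the reference allele (the tie rule below
makes that bias explicit and testable).

Stages, in order:

1. **Filtering** — each read is truncated at its first base with Phred
   quality below the threshold (default 30), so the retained prefix is
   uniformly above threshold; reads shorter than the per-library minimum
   (60 bp single-end, 50 bp mate-pair) are discarded. A mean-quality
   mode exists as an alternative. Mates filtered independently are
   re-paired; lone survivors continue as singletons (used for assembly
   and SNP mapping, not for pair-anchored backbone evidence).
2. **De novo assembly** — canonical-k-mer de Bruijn graph; k-mers seen
   fewer than `min_kmer_count` times (default 2) are pruned as errors;
   contigs are maximal non-branching paths (unitigs). There is no
   bubble popping or mate-pair scaffolding: heterozygous sites therefore
   fragment contigs at roughly one break per 1/(het rate) bases, which
   at the fixture's heterozygosity reproduces the ~1.2 kb contig-N50
   regime of real short-read data. k can be chosen by an exhaustive
   sweep (15–55 step 2) keeping the longest N50, ties to the larger k;
   on deep inputs the sweep can run on a read subsample with the winner
   re-assembled from everything.
3. **Reference alignment** — two tracks share a seed-and-extend engine
   (exact k-mer seeds from a sorted-array index, diagonal voting, affine
   gap DP via Bio.Align in query-global / target-local mode).
   *Contigs* ≥ 1 kb use a cheap-gap-extension preset; small instances
   get full-window DP (exact, equal to unbanded DP), long ones
   anchor-chained stitching with DP only between anchors. *Mate-pair
   reads* use a batched mapper: the best seed diagonal is verified by
   direct mismatch counting and accepted within a bounded edit fraction
   (default 0.1, mirroring an edit-distance-5 limit on 60 bp reads);
   reads whose mismatches cluster at an end — the signature of an
   unmodelled indel — are re-aligned with gaps. Insert size is
   estimated robustly (median/MAD then trimmed mean) from uniquely
   mapped, correctly oriented pairs; a pair is *proper* iff on one
   scaffold, in FR orientation, within mean ± 4 sd. Queries with a
   second placement within an absolute score margin are tiered
   "ambiguous" and excluded from consensus evidence.
4. **Backbone consensus** — contig and proper-pair alignments merge into
   one pileup (a contig base counts as one observation, same as a read
   base). Sites with depth below 0.5× or above 2× the mean are masked
   (the over-low/over-high coverage guard; the factors are a declared
   choice, surfaced in config). Each unmasked position takes the
   majority base if base support ≥ `min_depth` (default 1) and
   deletions do not outnumber the winner; ties go to the reference base
   when it is among the maxima, otherwise to the alphabetically smallest
   — the explicit reference-bias rule. Deletion-majority columns emit N.
5. **Gap filling** — all contigs ≥ 100 bp are aligned to the backbone;
   the backbone is also split into 10 kb fragments and mapped back onto
   itself (the literal round trip; a "direct" mode skips it). Only N
   positions can change, so the non-N count is monotonically
   non-decreasing by construction. Contigs mapping nowhere are screened
   against a decoy database (discard at ≥ 90% identity over ≥ half the
   contig) and the ≥ 200 bp survivors join the draft unplaced.
6. **SNP calling** — all filtered reads map back to the draft; columns
   within the coverage window (absolute 50–100X, or the mean-relative
   equivalent 0.85–1.75×mean for scaled runs) are scored with an
   explicit diallelic genotype-likelihood model: per-read error `e`
   (default 0.01), wrong bases uniform over the three alternatives, a
   heterozygote emitting either allele with probability 1/2, flat prior,
   phred-scaled genotype quality from the posterior. Only the draft
   base and the most frequent other base are modelled (tri-allelic
   columns reduced and counted). Columns within 10 bp of indel evidence
   (≥ 2 reads or 5% of depth showing a gap) are excluded — the
   varFilter-style guard; without it, indel-edge alignment artifacts
   dominate the false calls. Indels themselves are not called.
   Summaries: Ts/Tv (undefined marker when transversions are zero) and
   per-chromosome-class density as SNPs per non-N site, in percent.
7. **Comparative layer** — comparator genomes are cut into 10 kb
   pieces and aligned to the draft with near-free gap penalties; draft
   positions covered by more than one piece are excluded entirely, as
   are indel columns and N on either side. Divergence = variable /
   aligned sites in non-overlapping 50 kb tiles (an overlapping-step
   mode exists but is off: the published per-window coordinates are
   disjoint spans). Windows with under 10% aligned sites are undefined
   and excluded from means. Windows above the 0.2 cutoff (strictly
   greater) merge into regions, with overlapping genes attached; class
   means contrast the Z-classed scaffold against pooled autosomes
   (faster-Z ratio). Homologs come from reciprocal best hits at
   e-value ≤ 1e-10; hit tables are pluggable, and the built-in engine
   reports a nominal ungapped Karlin–Altschul e-value (λ=1.374, K=0.1
   for the +1/−3 scheme) — comparative, not calibrated. Because the
   built-in engine aligns the whole query, gene queries use their
   genomic span; spliced-CDS tables from a local-alignment engine drop
   in unchanged. CDS coverage is the non-N fraction of each gene's CDS
   intervals on the draft frame, histogrammed in 10% bins.

## Alignment scoring

Affine: `match` per identity, `−mismatch` per substitution,
`−(gap_open + gap_extend·L)` per gap. `N` scores 0 against anything so
gapped drafts can serve as alignment targets. Presets: *contig*
(1/−3, open 5, extend 1 — the cheap extension that tolerates the long
indel tracts expected between diverged genomes), *read* (1/−3, open 8,
extend 2, edit fraction ≤ 0.1), *piece* (1/−3, open 1, extend 1). The
piece preset accepts placements down to −0.5 per base: a genuinely
25%-divergent piece scores near 0 under +1/−3 while a spurious placement
scores near −2 per base, so the floor separates them without rejecting
the divergent regions the screen exists to find. Score equivalence with
external mapping tools is explicitly not claimed; what is claimed (and
tested) is equality with unbanded affine-gap DP on small instances.

## The synthetic fixture

The generator's defaults are the study conditions: three scaffolds
(two autosomes and one Z-classed, ~2 Mb total, GC 0.42), background
substitution rate 0.02 with a 2:1 transition bias, indels at 2e-4 with
geometric lengths (mean 3, capped at 50), a 50 kb island at rate 0.25,
Z at 1.5× the background rate, heterozygosity 1e-3 (also
transition-biased, so Ts/Tv recovery is testable), and three libraries —
75 bp single-end plus 60×60 bp mate pairs at 2 kb ± 200 and
5 kb ± 500 inserts, FR orientation, 20X each (60X aggregate), per-base
error 0.001 (the post-filter error level of the emulated platform),
constant Q40 qualities (a decaying profile exists to exercise the
filter). Every event is recorded in a truth channel with bidirectional
reference↔focal coordinate maps, and a reconciliation check proves that
each genome difference is explained by exactly one recorded event.

What the fixture does *not* emulate: repeats and repeat families,
PCR duplicates and chimeras, colour-space encoding, position-dependent
error spectra, rearrangements beyond optional planted inversions
(default off — the workflow avoids rearranged regions rather than
modelling them). Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its recovery of planted signal under clean
statistical assumptions, not robustness to repeat-rich real genomes.

## Problem sizes used in the tests and acceptance script

The test suite runs the full pipeline on a 500 kb instance of the
fixture (same composition, the divergence island scaled to keep its
2.5% genome share) and the acceptance script on a 1 Mb instance with
the full 50 kb island; both fix k = 31 — the sweep's winner on this
read design — while the sweep contract itself is tested on small
constructed fixtures. Divergence-recovery, faster-Z (20 seeded
replicates) and region-detection checks run the comparative layer on
substitution-only genomes with the true focal sequence standing in for
the draft, isolating those estimators from assembly incompleteness: on
an end-to-end draft the 25%-divergent island is largely unassembled
(reads and contigs from it do not map to the reference), which is the
expected behaviour of the method, so the screen's own recovery is
validated where the signal is representable.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only at
  SAM/VCF/GFF3 boundaries. BED outputs carry divergence ×1000 in the
  score column.
- Seeds: every stochastic operation takes an explicit seed; the
  pipeline derives per-stage seeds from the master seed via
  `SeedSequence.spawn`. Identical (inputs, config, seed) reproduce
  FASTA/VCF/BED outputs byte for byte.
- Consensus emits a single base at heterozygous columns (majority/tie
  rule), never ambiguity codes: the draft alphabet is A/C/G/T/N.
- `n50` is the largest L with contigs ≥ L summing to at least half the
  assembly; the k sweep's per-k table is emitted for inspection.
- Index k-mers containing N are not indexed; query seeds containing N
  are invalid. Read N bases are retained through filtering and are
  score-neutral in alignment.
- The reference-guided stages treat deletions relative to the reference
  conservatively: deletion-majority consensus columns become N, and
  the SNP caller skips deletion-dominant and gap-adjacent columns with
  counters, so the effect of each guard is inspectable in the run
  manifest.
- Restart points: the orchestrator persists contigs and the
  backbone/draft FASTA; with `--resume` it reloads whatever is present
  and recomputes downstream stages, reproducing the uninterrupted run's
  outputs exactly.

## Known limitations

- The unitig assembler intentionally lacks bubble popping, so diploid
  input fragments contigs at heterozygous sites; contiguity is bounded
  by 1/heterozygosity regardless of coverage.
- The read mapper's ungapped fast path bounds sensitivity for reads
  with more edits than the edit-fraction cap; such reads are dropped
  rather than soft-clipped.
- E-values from the built-in search engine are nominal; reciprocal-best
  logic and cutoffs are exact, but absolute significance should not be
  compared with external search tools.
- The faster-Z contrast assumes divergence windows are exchangeable
  within classes; no phylogenetic correction is attempted (tree
  estimation is out of scope).
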