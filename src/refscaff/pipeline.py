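"""End-to-end orchestration: simulate -> preprocess -> assemble -> align ->
scaffold -> variants -> compare, with persisted intermediates so any stage
can be resumed, and a reproducibility manifest.

Identical (inputs, config, seeds) reproduce identical FASTA/VCF/BED
outputs byte for byte; the manifest additionally records timings and
counters, which are excluded from that guarantee.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import align as al
from . import assemble as asm
from . import compare as cmp
from . import preprocess as pre
from . import scaffold as scf
from . import seqcodec
from . import simulate as sim
from . import variants as var
from .config import PipelineConfig, SimulationConfig
from .errors import PipelineError
from .genome import Genome
from .reads import LibrarySpec, ReadBatch
from .variants import ChromosomeClass


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Everything the pipeline consumes (paths are read once, up front)."""

    reference: Genome
    se_reads: Optional[ReadBatch] = None
    mp_libraries: List[Tuple[ReadBatch, ReadBatch]] = field(default_factory=list)
    comparators: Dict[str, Genome] = field(default_factory=dict)
    gene_models: list = field(default_factory=list)
    decoy: Optional[Genome] = None
    truth: Optional[sim.SimulationTruth] = None
    het_truth: Optional[dict] = None
    read_truths: Dict[str, pd.DataFrame] = field(default_factory=dict)
    focal: Optional[Genome] = None


def simulate_inputs(config: SimulationConfig, seed: int,
                    outdir: Optional[Path] = None) -> PipelineInputs:
    """Generate the full synthetic study fixture.

    Reference + evolved focal genome + diploid haplotypes + three read
    libraries (single-end and two mate-pair) + gene models + a decoy
    database, optionally written to ``outdir`` with all truth channels and
    a JSON manifest of seeds and specs.
    """
    rng_seeds = np.random.SeedSequence(seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng_seeds]

    ref = sim.generate_reference(
        len(config.scaffold_lengths), config.scaffold_lengths, config.gc,
        seeds[0], names=config.scaffold_names, chrom_classes=config.chrom_classes)
    seg = (config.divergent_segment_scaffold, config.divergent_segment_start,
           config.divergent_segment_start + config.divergent_segment_length,
           config.divergent_segment_rate)
    focal, truth = sim.evolve_genome(
        ref, config.sub_rate, config.indel_rate, [seg],
        z_multiplier=config.z_multiplier, seed=seeds[1], ts_bias=config.ts_bias)
    haps, het_truth = sim.make_diploid(focal, config.het_rate, seeds[2],
                                       ts_bias=config.ts_bias)

    se_spec = LibrarySpec(kind="single_end", read_length=config.se_read_length,
                          coverage=config.se_coverage,
                          error_rate=config.error_rate, name="se75")
    se_sim = sim.simulate_reads(haps, se_spec, seeds[3])
    mp_sims = []
    for i, (cov, mean, sd) in enumerate(zip(config.mp_coverages,
                                            config.mp_insert_means,
                                            config.mp_insert_sds)):
        spec = LibrarySpec(kind="mate_pair", read_length=config.mp_read_length,
                           coverage=cov, insert_mean=mean, insert_sd=sd,
                           error_rate=config.error_rate,
                           name=f"mp{mean // 1000}k")
        mp_sims.append(sim.simulate_reads(haps, spec, seeds[4 + i]))

    genes = sim.random_gene_models(ref, config.n_genes, seeds[6])
    decoy = sim.generate_reference(
        config.decoy_scaffolds,
        [config.decoy_length] * config.decoy_scaffolds,
        0.5, seeds[7], names=[f"decoy_{i + 1}" for i in range(config.decoy_scaffolds)])

    inputs = PipelineInputs(
        reference=ref,
        se_reads=se_sim.batches[0],
        mp_libraries=[(s.batches[0], s.batches[1]) for s in mp_sims],
        comparators={"reference": ref},
        gene_models=genes,
        decoy=decoy,
        truth=truth,
        het_truth=het_truth,
        read_truths={"se75": se_sim.truth,
                     **{s.library.name: s.truth for s in mp_sims}},
        focal=focal,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref.write_fasta(outdir / "reference.fasta")
        focal.write_fasta(outdir / "focal.fasta")
        haps[0].write_fasta(outdir / "haplotype1.fasta")
        haps[1].write_fasta(outdir / "haplotype2.fasta")
        decoy.write_fasta(outdir / "decoy.fasta")
        cmp.write_gene_models(outdir / "genes.gff3", genes)
        se_sim.write_fastq(outdir / "se75")
        for s in mp_sims:
            s.write_fastq(outdir / s.library.name)
        truth.write_tables(outdir / "truth")
        het = [df.assign(scaffold=name) for name, df in het_truth.items()]
        pd.concat(het, ignore_index=True).to_csv(
            outdir / "truth" / "het_sites_focal.tsv", sep="\t", index=False)
        manifest = {
            "seed": seed, "stage_seeds": seeds,
            "mate_pair_orientation": "FR",
            "libraries": [se_sim.manifest()] + [s.manifest() for s in mp_sims],
            "config": {k: v for k, v in config.__dict__.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return inputs


# ---------------------------------------------------------------------------
# result and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    draft: scf.DraftGenome
    backbone: List[scf.ConsensusScaffold]
    contigs: list
    snps: var.CallResult
    density: pd.DataFrame
    tstv: var.TsTvResult
    windows: pd.DataFrame
    regions: list
    class_table: pd.DataFrame
    faster_z: float
    rbh_pairs: list
    cds_table: pd.DataFrame
    manifest: dict
    insert_estimates: Dict[str, al.InsertEstimate] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageRunner:
    """Runs stages in order, timing them and recording counters."""

    def __init__(self, manifest: dict):
        self.manifest = manifest

    def run(self, name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate the failing stage
            raise PipelineError(
                f"stage {name!r} failed ({exc}); counters so far: "
                f"{self.manifest.get('counters', {})}") from exc
        self.manifest.setdefault("stages", []).append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 2)})
        return result


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 inputs: Optional[PipelineInputs] = None,
                 outdir=None,
                 resume: bool = False) -> PipelineResult:
    """Execute every stage on the given inputs (simulated when omitted).

    With ``outdir`` all declared outputs (draft FASTA, VCF, BED/TSV
    reports, manifest) and per-stage intermediates are written; with
    ``resume`` stages whose intermediates exist are reloaded instead of
    recomputed.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "counters": {}}
    counters = manifest["counters"]
    runner = _StageRunner(manifest)

    if inputs is None:
        inputs = runner.run("simulate", lambda: simulate_inputs(
            config.simulation, config.seed,
            outdir / "simulated" if outdir else None))
    reference = inputs.reference

    # ---- preprocess ------------------------------------------------------
    def stage_preprocess():
        se = None
        if inputs.se_reads is not None:
            res = pre.filter_reads(inputs.se_reads, config.quality_threshold,
                                   config.min_read_length_se)
            counters[f"filter_{res.report.library}"] = res.report.as_row()
            se = res.retained
        mp_pairs, singletons = [], []
        for m1, m2 in inputs.mp_libraries:
            r1 = pre.filter_reads(m1, config.quality_threshold,
                                  config.min_read_length_mp)
            r2 = pre.filter_reads(m2, config.quality_threshold,
                                  config.min_read_length_mp)
            lib = m1.library.name if m1.library else "mp"
            counters[f"filter_{lib}_1"] = r1.report.as_row()
            counters[f"filter_{lib}_2"] = r2.report.as_row()
            pair, single = pre.repair_pairs(r1.retained, r2.retained)
            counters[f"pairs_{lib}"] = {"pairs": pair[0].n, "singletons": single.n}
            mp_pairs.append(pair)
            singletons.append(single)
        return se, mp_pairs, singletons

    se_reads, mp_pairs, singletons = runner.run("preprocess", stage_preprocess)

    # ---- assemble --------------------------------------------------------
    def stage_assemble():
        contig_path = outdir / "contigs.fasta" if outdir else None
        if resume and contig_path is not None and contig_path.exists():
            return asm.read_contigs_fasta(contig_path)
        batches = [b for b in [se_reads] if b is not None]
        for p1, p2 in mp_pairs:
            batches.extend([p1, p2])
        batches.extend(b for b in singletons if b.n)
        if config.k_fixed is not None:
            contigs = asm.build_contigs(batches, config.k_fixed,
                                        config.min_contig_length,
                                        config.min_kmer_count)
        else:
            result = asm.select_k(batches, config.k_min, config.k_max,
                                  config.k_step, config.min_contig_length,
                                  config.min_kmer_count,
                                  subsample_fraction=config.sweep_subsample,
                                  seed=config.seed)
            counters["best_k"] = result.best_k
            if outdir:
                result.stats.to_csv(outdir / "assembly_k_sweep.tsv",
                                    sep="\t", index=False)
            contigs = result.contigs
        stats = asm.AssemblyStats.from_contigs(contigs)
        counters["assembly"] = stats.__dict__
        if contig_path is not None:
            asm.write_contigs_fasta(contig_path, contigs)
        return contigs

    contigs = runner.run("assemble", stage_assemble)

    # resume point: a persisted draft short-circuits align + scaffold
    draft_ready = (resume and outdir is not None
                   and (outdir / "draft.fasta").exists()
                   and (outdir / "backbone.fasta").exists())

    # ---- align -----------------------------------------------------------
    def stage_align():
        if draft_ready:
            return [], {}, [], {}, set()
        contig_params = al.contig_preset()
        read_params = al.read_preset()
        contig_index = al.SeqIndex(reference, contig_params.seed_length)
        read_index = al.SeqIndex(reference, read_params.seed_length)
        contig_records, contig_queries = [], {}
        mapped_to_ref = set()
        for contig in contigs:
            if len(contig) < config.min_contig_for_reference_mapping:
                continue
            recs = al.align_long(contig, contig_index, contig_params)
            if recs:
                mapped_to_ref.add(contig.id)
                if recs[0].mapq_proxy == al.UNIQUE:
                    contig_records.append(recs[0])
                    contig_queries[contig.id] = contig
        counters["contigs_mapped_to_reference"] = len(mapped_to_ref)

        pair_alignments, inserts = [], {}
        for (p1, p2) in mp_pairs:
            a1, a2, est = al.align_pairs((p1, p2), read_index, read_params,
                                         k_sd=config.pair_k_sd)
            lib = p1.library.name if p1.library else "mp"
            inserts[lib] = est
            counters[f"mapped_{lib}"] = {
                "mate1": a1.n_mapped, "mate2": a2.n_mapped,
                "proper_pairs": int(np.sum(a1.pair_state == 1)),
                "insert_mean": round(est.mean, 1), "insert_sd": round(est.sd, 1),
            }
            pair_alignments.extend([a1, a2])
        return contig_records, contig_queries, pair_alignments, inserts, mapped_to_ref

    (contig_records, contig_queries, pair_alignments,
     inserts, mapped_to_ref) = runner.run("align", stage_align)

    # ---- scaffold --------------------------------------------------------
    def stage_scaffold():
        if draft_ready:
            bb_records = seqcodec.read_fasta(outdir / "backbone.fasta")
            loaded_backbone = [scf.ConsensusScaffold(name, seq, name, "backbone")
                               for name, seq in bb_records]
            scaffold_names = {name for name, _ in bb_records}
            loaded_scaffolds, loaded_unplaced = [], []
            from .assemble import Contig as _Contig
            for name, seq in seqcodec.read_fasta(outdir / "draft.fasta"):
                if name in scaffold_names:
                    loaded_scaffolds.append(
                        scf.ConsensusScaffold(name, seq, name, "final"))
                else:
                    loaded_unplaced.append(_Contig(name, seq, 1.0, 0))
            loaded_draft = scf.DraftGenome(
                scaffolds=loaded_scaffolds, unplaced_contigs=loaded_unplaced,
                manifest={"reference_scaffolds": reference.names},
                chrom_class_map=dict(reference.chrom_class_map))
            profile, _per_scaffold, _windows = scf.assembly_profile(loaded_draft)
            counters["draft"] = {
                "scaffolds": len(loaded_draft.scaffolds),
                "sequenced": profile.sequenced_total,
                "gaps": profile.n_total,
                "sequenced_blocks": int(profile.sequenced_block_lengths.size),
                "resumed": True,
            }
            return loaded_backbone, loaded_draft
        evidence = scf.merge_evidence(contig_records, contig_queries,
                                      pair_alignments, reference)
        masks, mean_depth = al.coverage_filter(evidence,
                                               config.coverage_low_factor,
                                               config.coverage_high_factor)
        counters["backbone_mean_depth"] = round(mean_depth, 2)
        backbone = scf.consensus(evidence, reference,
                                 min_depth=config.consensus_min_depth,
                                 coverage_mask=masks)
        counters["backbone_non_n"] = {s.name: s.non_n() for s in backbone}
        gf = scf.gap_fill(backbone, contigs,
                          min_contig_length=config.min_contig_for_gapfill,
                          self_fragment_size=config.self_fragment_size,
                          mode=config.gapfill_mode)
        counters["gapfill_filled"] = gf.filled_positions
        mapped = gf.mapped_contig_ids | mapped_to_ref
        unmapped = [c for c in contigs if c.id not in mapped]
        kept, discarded = scf.screen_unplaced(unmapped, inputs.decoy,
                                              min_length=config.min_unplaced_contig)
        counters["unplaced_kept"] = len(kept)
        counters["unplaced_discarded_contamination"] = len(discarded)
        draft = scf.DraftGenome(
            scaffolds=gf.scaffolds, unplaced_contigs=kept,
            manifest={"reference_scaffolds": reference.names},
            chrom_class_map=dict(reference.chrom_class_map))
        profile, per_scaffold, windows = scf.assembly_profile(draft)
        counters["draft"] = {
            "scaffolds": len(draft.scaffolds),
            "sequenced": profile.sequenced_total,
            "gaps": profile.n_total,
            "sequenced_blocks": int(profile.sequenced_block_lengths.size),
        }
        if outdir:
            seqcodec.write_fasta(outdir / "backbone.fasta",
                                 [(s.name, s.sequence) for s in backbone])
            draft.write_fasta(outdir / "draft.fasta")
            per_scaffold.to_csv(outdir / "draft_coverage.tsv", sep="\t", index=False)
            scf.write_window_bed(outdir / "draft_windows.bed", windows)
        return backbone, draft

    backbone, draft = runner.run("scaffold", stage_scaffold)
    draft_genome = draft.to_genome()

    # ---- variants --------------------------------------------------------
    def stage_variants():
        read_params = al.read_preset()
        index = al.SeqIndex(draft_genome, read_params.seed_length)
        counts = al.new_pileup(draft_genome)
        batches = [b for b in [se_reads] if b is not None]
        for p1, p2 in mp_pairs:
            batches.extend([p1, p2])
        batches.extend(b for b in singletons if b.n)
        mapped_reads = 0
        for batch in batches:
            aln = al.map_reads(batch, index, read_params)
            mapped_reads += aln.n_mapped
            al.add_read_alignments(counts, aln)
        counters["reads_mapped_to_draft"] = mapped_reads
        calling = var.CallingConfig(
            cov_min=config.cov_min, cov_max=config.cov_max,
            base_error=config.base_error,
            min_genotype_quality=config.min_genotype_quality,
            mean_relative=config.cov_mean_relative)
        result = var.call_snps(counts, draft_genome, calling)
        counters["snp_calling"] = {**result.counters,
                                   "mean_depth": round(result.mean_depth, 2),
                                   "n_snps": len(result.snps)}
        classes = var.default_classes(draft_genome)
        density = var.snp_density(result.snps, draft_genome, classes)
        ratio = var.tstv(result.snps)
        if outdir:
            var.write_vcf(outdir / "snps.vcf", result.snps, draft_genome)
            density.to_csv(outdir / "snp_density.tsv", sep="\t", index=False)
        return result, density, ratio

    snp_result, density, tstv_result = runner.run("variants", stage_variants)

    # ---- compare ---------------------------------------------------------
    def stage_compare():
        piece_params = al.piece_preset()
        index = al.SeqIndex(draft_genome, piece_params.seed_length)
        all_windows = []
        for comp_name, comp_genome in inputs.comparators.items():
            pieces = cmp.fragment_genome(comp_genome, config.piece_size)
            calls = cmp.piecewise_divergence(pieces, draft_genome, piece_params,
                                             comparator=comp_name, index=index)
            counters[f"pieces_{comp_name}"] = {
                "total": calls.n_pieces, "mapped": calls.n_pieces_mapped}
            all_windows.append(cmp.window_divergence(
                calls, config.window_size, config.min_aligned_fraction))
        windows = pd.concat(all_windows, ignore_index=True)
        regions = cmp.flag_divergent(windows, config.divergence_cutoff,
                                     inputs.gene_models)
        classes = var.default_classes(draft_genome)
        class_table, faster_z = cmp.class_divergence(windows, classes)
        counters["divergent_regions"] = len(regions)
        counters["faster_z_ratio"] = (round(faster_z, 3)
                                      if not np.isnan(faster_z) else None)

        rbh_pairs, cds_table = [], pd.DataFrame()
        if inputs.gene_models:
            # the built-in engine aligns the full query, so gene queries use
            # the genomic span (introns included); a local-alignment engine
            # could supply spliced-CDS hit tables instead
            gene_seqs = gene_span_sequences(inputs.gene_models, reference)
            fwd = cmp.search_hits(gene_seqs, draft_genome, piece_params, index=index)
            gene_db = Genome([(gid, seq) for gid, seq in gene_seqs.items()])
            region_seqs = {}
            for _, row in fwd.sort_values(["query", "evalue"]).drop_duplicates("query").iterrows():
                codes = draft_genome.codes(row["scaffold"])[row["start"]:row["end"]]
                region_seqs[row["subject"]] = seqcodec.decode(codes)
            rev = cmp.search_hits(region_seqs, gene_db, piece_params)
            if not rev.empty:
                rev = rev.assign(subject=rev["scaffold"])  # subject = gene id
            rbh_pairs = cmp.reciprocal_best_hits(fwd, rev, config.evalue_cutoff)
            cds_table, hist, over_90 = cmp.cds_coverage(inputs.gene_models,
                                                        draft_genome)
            counters["annotation"] = {
                "genes": len(inputs.gene_models), "rbh": len(rbh_pairs),
                "cds_over_90pct": over_90,
                "cds_histogram": hist.tolist()}
        if outdir:
            windows.to_csv(outdir / "divergence_windows.tsv", sep="\t", index=False)
            cmp.write_windows_bed(outdir / "divergence_windows.bed", windows)
            cmp.write_regions_bed(outdir / "divergent_regions.bed", regions)
            class_table.to_csv(outdir / "class_divergence.tsv", sep="\t", index=False)
            if not cds_table.empty:
                cds_table.to_csv(outdir / "cds_coverage.tsv", sep="\t", index=False)
            if rbh_pairs:
                pd.DataFrame([p.__dict__ for p in rbh_pairs]).to_csv(
                    outdir / "rbh_pairs.tsv", sep="\t", index=False)
        return windows, regions, class_table, faster_z, rbh_pairs, cds_table

    (windows, regions, class_table, faster_z,
     rbh_pairs, cds_table) = runner.run("compare", stage_compare)

    if outdir:
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(outdir.glob("*"))
            if p.is_file() and p.suffix in (".fasta", ".vcf", ".bed", ".tsv")}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))

    return PipelineResult(
        draft=draft, backbone=backbone, contigs=contigs, snps=snp_result,
        density=density, tstv=tstv_result, windows=windows, regions=regions,
        class_table=class_table, faster_z=faster_z, rbh_pairs=rbh_pairs,
        cds_table=cds_table, manifest=manifest, insert_estimates=inserts)


def gene_cds_sequences(gene_models, genome: Genome) -> Dict[str, str]:
    """Spliced CDS sequence of each gene on its genome (forward strand)."""
    out = {}
    for gene in gene_models:
        codes = genome.codes(gene.scaffold)
        spliced = np.concatenate([codes[s:e] for s, e in gene.cds_intervals])
        if gene.strand == "-":
            spliced = seqcodec.revcomp(spliced)
        out[gene.gene_id] = seqcodec.decode(spliced)
    return out


def gene_span_sequences(gene_models, genome: Genome) -> Dict[str, str]:
    """Genomic span (first to last CDS base, introns included) per gene."""
    out = {}
    for gene in gene_models:
        start, end = gene.span
        codes = genome.codes(gene.scaffold)[start:end]
        if gene.strand == "-":
            codes = seqcodec.revcomp(codes)
        out[gene.gene_id] = seqcodec.decode(codes)
    return out
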