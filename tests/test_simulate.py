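"""The generator must plant exactly what it records and nothing else."""

import numpy as np
import pytest

from refscaff import seqcodec
from refscaff import simulate as sim
from refscaff.errors import ParameterError
from refscaff.genome import Genome
from refscaff.reads import LibrarySpec


class TestGenerateReference:
    @pytest.mark.parametrize("args", [
        (1, [0], 0.5),          # empty scaffold forbidden
        (1, [1000], 0.0),       # gc bound
        (1, [1000], 1.0),
        (2, [1000], 0.5),       # length list mismatch
        (1, [-5], 0.5),
    ])
    def test_parameter_errors(self, args):
        n, lengths, gc = args
        with pytest.raises(ParameterError):
            sim.generate_reference(n, lengths, gc, seed=1)

    def test_seeded_determinism_bytewise(self, tmp_path):
        paths = []
        for i in (1, 2):
            g = sim.generate_reference(2, [10_000, 5_000], 0.45, seed=7)
            p = tmp_path / f"ref{i}.fasta"
            g.write_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_fraction_within_binomial_noise(self):
        L = 200_000
        gc = 0.40
        g = sim.generate_reference(1, [L], gc, seed=3)
        codes = g.codes("scaffold_1")
        observed = int(np.sum((codes == seqcodec.C) | (codes == seqcodec.G)))
        sd = np.sqrt(L * gc * (1 - gc))
        assert abs(observed - L * gc) < 3 * sd

    def test_z_class_tag(self):
        g = sim.generate_reference(2, [1000, 1000], 0.5, seed=1,
                                   chrom_classes=["macro", "Z"])
        assert g.chrom_class_map["scaffold_2"] == "Z"


class TestEvolveGenome:
    def test_zero_rates_identity(self, small_reference):
        focal, truth = sim.evolve_genome(small_reference, 0.0, 0.0, seed=5)
        for name in small_reference.names:
            assert focal.sequence(name) == small_reference.sequence(name)
            assert len(truth.substitutions[name]) == 0
        assert truth.indel_events == []

    def test_substitution_rate_recovered(self):
        L = 100_000
        rate = 0.02
        ref = sim.generate_reference(1, [L], 0.5, seed=21)
        focal, _ = sim.evolve_genome(ref, rate, 0.0, seed=22)
        mism = int(np.sum(ref.codes("scaffold_1") != focal.codes("scaffold_1")))
        sd = np.sqrt(L * rate * (1 - rate))
        assert abs(mism - L * rate) < 3 * sd

    def test_zero_indel_rate_preserves_length(self, small_reference):
        focal, _ = sim.evolve_genome(small_reference, 0.05, 0.0, seed=9)
        assert focal.lengths == small_reference.lengths

    def test_divergent_segment_rates(self):
        ref = sim.generate_reference(1, [150_000], 0.5, seed=31)
        seg = ("scaffold_1", 50_000, 100_000, 0.25)
        focal, truth = sim.evolve_genome(ref, 0.02, 0.0, [seg], seed=32)
        r, f = ref.codes("scaffold_1"), focal.codes("scaffold_1")
        # zero indels: the coordinate map is the identity
        assert np.array_equal(truth.ref_to_focal["scaffold_1"],
                              np.arange(150_000))
        inside = np.mean(r[50_000:100_000] != f[50_000:100_000])
        outside = np.mean(np.concatenate([r[:50_000] != f[:50_000],
                                          r[100_000:] != f[100_000:]]))
        assert inside > 0.2
        assert outside < 0.05

    def test_overlapping_segments_rejected(self, small_reference):
        segs = [("chr1", 0, 1000, 0.2), ("chr1", 500, 2000, 0.2)]
        with pytest.raises(ParameterError):
            sim.evolve_genome(small_reference, 0.02, 0.0, segs, seed=1)

    def test_z_multiplier_elevates_z_rate(self):
        ref = sim.generate_reference(2, [100_000, 100_000], 0.5, seed=41,
                                     names=["auto", "sex"],
                                     chrom_classes=["macro", "Z"])
        focal, _ = sim.evolve_genome(ref, 0.02, 0.0, z_multiplier=1.5, seed=42)
        auto = np.mean(ref.codes("auto") != focal.codes("auto"))
        z = np.mean(ref.codes("sex") != focal.codes("sex"))
        assert 1.2 < z / auto < 1.8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_truth_reconciles_with_indels(self, seed):
        ref = sim.generate_reference(2, [60_000, 40_000], 0.45, seed=seed)
        focal, truth = sim.evolve_genome(ref, 0.02, 5e-4, seed=seed + 100)
        sim.verify_truth(ref, focal, truth)  # raises on any unexplained diff

    def test_inversion_recorded_and_mapped(self):
        ref = sim.generate_reference(1, [20_000], 0.5, seed=51)
        focal, truth = sim.evolve_genome(ref, 0.0, 0.0, seed=52,
                                         inversions=[("scaffold_1", 5000, 6000)])
        seg = focal.codes("scaffold_1")[5000:6000]
        expected = seqcodec.revcomp(ref.codes("scaffold_1")[5000:6000])
        assert np.array_equal(seg, expected)
        assert len(truth.inversion_events) == 1


class TestMakeDiploid:
    def test_zero_rate_identical_haplotypes(self, evolved):
        focal, _ = evolved
        (h1, h2), het = sim.make_diploid(focal, 0.0, seed=1)
        for name in focal.names:
            assert h1.sequence(name) == h2.sequence(name) == focal.sequence(name)
            assert len(het[name]) == 0

    def test_site_count_within_binomial_noise(self):
        L = 1_000_000
        ref = sim.generate_reference(1, [L], 0.5, seed=61)
        (h1, h2), het = sim.make_diploid(ref, 0.001, seed=62)
        n = len(het["scaffold_1"])
        sd = np.sqrt(L * 0.001)
        assert abs(n - 1000) < 3 * sd

    def test_haplotypes_differ_exactly_at_recorded_sites(self, diploid, evolved):
        (h1, h2), het = diploid
        focal, _ = evolved
        for name in focal.names:
            c1, c2 = h1.codes(name), h2.codes(name)
            diff = np.flatnonzero(c1 != c2)
            df = het[name]
            assert np.array_equal(diff, np.sort(df["position"].to_numpy()))
            for _, row in df.iterrows():
                p = int(row["position"])
                assert seqcodec.decode(c1[p:p + 1]) == row["allele1"]
                assert seqcodec.decode(c2[p:p + 1]) == row["allele2"]
                assert row["allele1"] != row["allele2"]

    def test_rate_bound(self, evolved):
        focal, _ = evolved
        with pytest.raises(ParameterError):
            sim.make_diploid(focal, 0.2, seed=1)


class TestSimulateReads:
    def test_read_count_from_coverage(self):
        g = Genome([("s", "ACGT" * 250)])  # 1000 bp
        spec = LibrarySpec(kind="single_end", read_length=100, coverage=10,
                           error_rate=0.0)
        reads = sim.simulate_reads(g, spec, seed=1)
        assert reads.batches[0].n == 100

    def test_error_free_reads_match_origin(self, diploid, se_library):
        haps, _ = diploid
        spec = LibrarySpec(kind="single_end", read_length=75, coverage=2,
                           error_rate=0.0, name="clean")
        reads = sim.simulate_reads(haps, spec, seed=3)
        batch = reads.batches[0]
        for i in range(0, batch.n, 37):
            row = reads.truth.iloc[i]
            hap = haps[int(row["haplotype"])]
            origin = hap.codes(row["scaffold"])[row["position"]:row["position"] + 75]
            got = batch.codes[i, :75]
            if row["strand"] == "-":
                got = seqcodec.revcomp(got)
            assert np.array_equal(got, origin)

    def test_error_rate_within_binomial_noise(self, diploid):
        haps, _ = diploid
        spec = LibrarySpec(kind="single_end", read_length=75, coverage=5,
                           error_rate=0.01, name="noisy")
        reads = sim.simulate_reads(haps, spec, seed=7)
        batch = reads.batches[0]
        mismatches = 0
        total = 0
        for i in range(batch.n):
            row = reads.truth.iloc[i]
            hap = haps[int(row["haplotype"])]
            origin = hap.codes(row["scaffold"])[row["position"]:row["position"] + 75]
            got = batch.codes[i, :75]
            if row["strand"] == "-":
                got = seqcodec.revcomp(got)
            mismatches += int(np.sum(got != origin))
            total += 75
            if total >= 150_000:
                break
        expected = total * 0.01
        sd = np.sqrt(expected)
        assert abs(mismatches - expected) < 3 * sd

    def test_mate_pair_fr_orientation(self, diploid):
        haps, _ = diploid
        spec = LibrarySpec(kind="mate_pair", read_length=60, coverage=1,
                           insert_mean=2000, insert_sd=100, error_rate=0.0,
                           name="mp")
        reads = sim.simulate_reads(haps, spec, seed=9)
        m1, m2 = reads.batches
        truth = reads.truth
        t1 = truth[truth["mate"] == 1].set_index("read_index")
        t2 = truth[truth["mate"] == 2].set_index("read_index")
        for i in range(0, m1.n, 53):
            r1, r2 = t1.loc[i], t2.loc[i]
            assert r1["scaffold"] == r2["scaffold"]
            assert {r1["strand"], r2["strand"]} == {"+", "-"}
            fwd, rev = (r1, r2) if r1["strand"] == "+" else (r2, r1)
            assert fwd["position"] <= rev["position"]  # innie orientation
            hap = haps[int(r1["haplotype"])]
            codes = hap.codes(r1["scaffold"])
            exp1 = codes[r1["position"]:r1["position"] + 60]
            got1 = m1.codes[i, :60]
            if r1["strand"] == "-":
                got1 = seqcodec.revcomp(got1)
            assert np.array_equal(got1, exp1)

    def test_insert_longer_than_scaffold_rejected(self):
        g = Genome([("s", "ACGT" * 300)])  # 1200 bp
        spec = LibrarySpec(kind="mate_pair", read_length=60, coverage=1,
                           insert_mean=2000, insert_sd=100, error_rate=0.0)
        with pytest.raises(ParameterError):
            sim.simulate_reads(g, spec, seed=1)

    def test_seeded_determinism(self, diploid, se_library):
        haps, _ = diploid
        a = sim.simulate_reads(haps, se_library, seed=42)
        b = sim.simulate_reads(haps, se_library, seed=42)
        assert np.array_equal(a.batches[0].codes, b.batches[0].codes)
        assert a.truth.equals(b.truth)


class TestGeneModels:
    def test_planted_genes_are_well_formed(self, small_reference):
        genes = sim.random_gene_models(small_reference, 8, seed=5)
        assert genes
        for gene in genes:
            start, end = gene.span
            assert 0 <= start < end <= small_reference.lengths[gene.scaffold]
            for (s1, e1), (s2, _) in zip(gene.cds_intervals,
                                         gene.cds_intervals[1:]):
                assert e1 <= s2
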