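"""Alignment scores against unbanded DP, pair logic, pileups, coverage."""

import numpy as np
import pytest

from oracles import brute_pileup, glocal_dp_score

from refscaff import align as al
from refscaff import seqcodec
from refscaff import simulate as sim
from refscaff.errors import IntegrityError
from refscaff.genome import Genome
from refscaff.reads import LibrarySpec, ReadBatch

from conftest import random_sequence


def _mutate(seq, n_subs, seed, indels=()):
    rng = np.random.default_rng(seed)
    codes = seqcodec.encode(seq)
    for p in rng.choice(codes.size, size=n_subs, replace=False):
        codes[p] = (codes[p] + 1 + rng.integers(0, 3)) % 4
    seq = seqcodec.decode(codes)
    for pos, length, kind in sorted(indels, reverse=True):
        if kind == "del":
            seq = seq[:pos] + seq[pos + length:]
        else:
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


@pytest.fixture(scope="module")
def target():
    return Genome([("chr1", random_sequence(20_000, seed=1))])


@pytest.fixture(scope="module")
def index(target):
    return al.SeqIndex(target, 15)


class TestAlignLong:
    def test_exact_substring_single_full_match(self, target, index):
        query = target.sequence("chr1")[5000:6000]
        recs = al.align_long(query, index, al.contig_preset())
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.target_start, rec.strand) == (5000, "+")
        assert rec.cigar == [("M", 1000)]
        assert rec.score == 1000
        assert rec.mapq_proxy == al.UNIQUE

    def test_reverse_complement_same_locus_minus_strand(self, target, index):
        query = seqcodec.decode(
            seqcodec.revcomp(seqcodec.encode(target.sequence("chr1")[5000:6000])))
        rec = al.align_long(query, index, al.contig_preset())[0]
        assert (rec.target_start, rec.strand) == (5000, "-")
        assert rec.score == 1000

    @pytest.mark.parametrize("preset", [al.contig_preset, al.read_preset])
    @pytest.mark.parametrize("case", range(6))
    def test_score_equals_unbanded_dp_oracle(self, preset, case):
        """On small instances the reported score is the exact DP optimum."""
        rng = np.random.default_rng(100 + case)
        target_seq = random_sequence(2000, seed=200 + case)
        qlen = int(rng.integers(150, 301))
        start = int(rng.integers(0, 2000 - qlen))
        indels = []
        if case % 2:
            indels = [(int(rng.integers(20, qlen - 20)),
                       int(rng.integers(1, 4)), "del" if case % 4 == 1 else "ins")]
        query = _mutate(target_seq[start:start + qlen],
                        n_subs=int(rng.integers(0, 8)), seed=case, indels=indels)
        params = preset()
        target = Genome([("t", target_seq)])
        recs = al.align_long(query, al.SeqIndex(target, params.seed_length), params)
        assert recs, "query must be placeable"
        expected = glocal_dp_score(query, target_seq,
                                   match=params.match, mismatch=params.mismatch,
                                   gap_open=params.gap_open,
                                   gap_extend=params.gap_extend)
        assert recs[0].score == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_strand_involution(self, target, index, seed):
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, 19_000))
        query = _mutate(target.sequence("chr1")[start:start + 500], 10, seed)
        fwd = al.align_long(query, index, al.contig_preset())[0]
        rc = seqcodec.decode(seqcodec.revcomp(seqcodec.encode(query)))
        rev = al.align_long(rc, index, al.contig_preset())[0]
        assert fwd.score == rev.score
        assert {fwd.strand, rev.strand} == {"+", "-"}
        assert fwd.target_start == rev.target_start

    def test_duplicated_region_is_ambiguous(self):
        block = random_sequence(1500, seed=5)
        genome = Genome([("dup", random_sequence(500, seed=6) + block
                          + random_sequence(500, seed=7) + block)])
        query = block[200:1200]
        recs = al.align_long(query, al.SeqIndex(genome, 15), al.contig_preset())
        assert len(recs) >= 2
        assert recs[0].mapq_proxy == al.AMBIGUOUS

    def test_unplaceable_query_returns_empty(self, index):
        assert al.align_long(random_sequence(500, seed=8), index,
                             al.contig_preset()) == []

    def test_min_query_length_gate(self, target, index):
        query = target.sequence("chr1")[100:400]
        assert al.align_long(query, index, al.contig_preset(),
                             min_query_length=1000) == []


@pytest.fixture(scope="module")
def setup():
    genome = Genome([("chr1", random_sequence(30_000, seed=9)),
                     ("chr2", random_sequence(20_000, seed=10))])
    spec = LibrarySpec(kind="single_end", read_length=75, coverage=4,
                       error_rate=0.0, name="t")
    reads = sim.simulate_reads(genome, spec, seed=11)
    index = al.SeqIndex(genome, 13)
    return genome, reads, index


class TestMapReads:
    def test_error_free_reads_recover_planted_positions(self, setup):
        genome, reads, index = setup
        aln = al.map_reads(reads.batches[0], index, al.read_preset())
        truth = reads.truth
        mapped = aln.scaffold >= 0
        assert mapped.mean() > 0.95
        names = index.names
        correct = 0
        for i in np.flatnonzero(mapped):
            row = truth.iloc[i]
            if (names[aln.scaffold[i]] == row["scaffold"]
                    and aln.pos[i] == row["position"]
                    and (aln.strand[i] > 0) == (row["strand"] == "+")):
                correct += 1
        assert correct / mapped.sum() > 0.99
        assert np.all(aln.nm[mapped & (aln.tier == 0)] == 0)

    def test_read_with_indel_recovered_by_gapped_fallback(self, setup):
        genome, _, index = setup
        base = genome.sequence("chr1")[1000:1075]
        query = base[:40] + base[43:]  # 3 bp deletion mid-read
        batch = ReadBatch(
            codes=seqcodec.encode(query)[None, :],
            quals=np.full((1, len(query)), 40, np.uint8),
            lengths=np.array([len(query)], dtype=np.int32))
        aln = al.map_reads(batch, index, al.read_preset())
        assert aln.scaffold[0] >= 0
        assert aln.pos[0] == 1000
        assert any(op == "D" for op, _ in aln.cigars.get(0, []))


@pytest.fixture(scope="module")
def genome():
    return Genome([("chr1", random_sequence(120_000, seed=12))])


class TestAlignPairs:
    def _make_pair_batch(self, genome, placements, read_length=60):
        """Construct synchronized mate batches from explicit placements.

        placements: list of (scaffold, pos1, pos2) with mate1 forward at
        pos1 and mate2 reverse-complemented at pos2.
        """
        lib = LibrarySpec(kind="mate_pair", read_length=read_length,
                          coverage=1, insert_mean=2000, insert_sd=100,
                          error_rate=0.0, name="mp")
        c1, c2 = [], []
        for scaf, p1, p2 in placements:
            codes = genome.codes(scaf)
            c1.append(codes[p1:p1 + read_length])
            c2.append(seqcodec.revcomp(codes[p2:p2 + read_length]))
        n = len(placements)
        mk = lambda rows, tag: ReadBatch(
            codes=np.stack(rows), quals=np.full((n, read_length), 40, np.uint8),
            lengths=np.full(n, read_length, np.int32),
            pair_ids=np.arange(n), mate_tag=tag, library=lib)
        return mk(c1, 1), mk(c2, 2)

    def test_planted_separations_classified(self, genome):
        rng = np.random.default_rng(13)
        placements = []
        for _ in range(300):
            p1 = int(rng.integers(0, 100_000))
            insert = int(np.clip(rng.normal(2000, 100), 1500, 2500))
            placements.append(("chr1", p1, p1 + insert - 60))
        placements.append(("chr1", 100, 100_000))  # far-apart pair
        m1, m2 = self._make_pair_batch(genome, placements)
        a1, a2, est = al.align_pairs((m1, m2), al.SeqIndex(genome, 13),
                                     al.read_preset())
        assert a1.pair_state[:-1].tolist().count(1) >= 295
        assert a1.pair_state[-1] == 2  # discordant
        # insert estimate within 3 standard errors of the planted mean
        se = 100 / np.sqrt(est.n_used)
        assert abs(est.mean - 2000) < 3 * se + 1
        assert est.from_spec is False

    def test_too_few_pairs_falls_back_to_library_values(self, genome):
        placements = [("chr1", 1000, 2940)]
        m1, m2 = self._make_pair_batch(genome, placements)
        with pytest.warns(UserWarning):
            a1, _a2, est = al.align_pairs((m1, m2), al.SeqIndex(genome, 13),
                                          al.read_preset())
        assert est.from_spec is True
        assert est.mean == 2000
        assert a1.pair_state[0] == 1


class TestPileup:
    def test_no_records_no_depth(self):
        genome = Genome([("s", "ACGT" * 100)])
        counts = al.new_pileup(genome)
        assert not list(al.iter_pileup_columns(counts, "s"))

    def test_single_perfect_read_interval(self):
        genome = Genome([("s", random_sequence(200, seed=14))])
        counts = al.new_pileup(genome)
        codes = genome.codes("s")[10:70]
        al._add_cigar_observation(counts["s"], codes, 10, [("M", 60)])
        depth = counts["s"].sum(axis=0)
        assert np.all(depth[10:70] == 1)
        assert depth[:10].sum() == 0 and depth[70:].sum() == 0

    def test_overlapping_records_match_brute_force(self):
        genome = Genome([("s", random_sequence(300, seed=15))])
        rng = np.random.default_rng(16)
        observations = []
        for start, cigar in [
            (0, [("M", 50)]),
            (30, [("M", 20), ("D", 5), ("M", 25)]),
            (40, [("S", 5), ("M", 30), ("I", 4), ("M", 21)]),
        ]:
            qlen = sum(n for op, n in cigar if op in "MIS")
            observations.append((start,
                                 rng.integers(0, 4, qlen).astype(np.uint8),
                                 cigar))
        counts = al.new_pileup(genome)
        for start, codes, cigar in observations:
            al._add_cigar_observation(counts["s"], codes, start, cigar)
        assert np.array_equal(counts["s"][:6],
                              brute_pileup(300, observations).astype(np.uint32))

    def test_batch_pileup_conserves_aligned_bases(self):
        genome = Genome([("chr1", random_sequence(10_000, seed=17))])
        spec = LibrarySpec(kind="single_end", read_length=75, coverage=8,
                           error_rate=0.0)
        reads = sim.simulate_reads(genome, spec, seed=18)
        index = al.SeqIndex(genome, 13)
        aln = al.map_reads(reads.batches[0], index, al.read_preset())
        counts = al.new_pileup(genome)
        added = al.add_read_alignments(counts, aln)
        mapped_unique = (aln.scaffold >= 0) & (aln.tier == 0)
        expected = int(aln.batch.lengths[mapped_unique].sum())
        assert added == expected
        assert int(counts["chr1"][:5].sum()) == expected

    def test_column_stream_from_records(self):
        genome = Genome([("s", random_sequence(100, seed=30))])
        seq = genome.sequence("s")[20:60]
        rec = al.AlignmentRecord("q", "s", 20, "+", [("M", 40)], 40,
                                 query_sequence=seq)
        columns = list(al.pileup_from_alignments([rec], genome))
        assert len(columns) == 40
        assert columns[0].position == 20
        assert all(c.depth == 1 for c in columns)

    def test_overrun_raises_integrity_error(self):
        genome = Genome([("s", "ACGT" * 10)])
        counts = al.new_pileup(genome)
        with pytest.raises(IntegrityError):
            al._add_cigar_observation(counts["s"],
                                      np.zeros(60, np.uint8), 30, [("M", 60)])


class TestCoverageFilter:
    def test_uniform_depth_nothing_masked(self):
        genome = Genome([("s", "A" * 500)])
        counts = {"s": np.zeros((6, 500), np.uint32)}
        counts["s"][0, :] = 30
        masks, mean = al.coverage_filter(counts)
        assert mean == 30
        assert masks["s"].all()

    def test_depth_spike_masked(self):
        counts = {"s": np.zeros((6, 500), np.uint32)}
        counts["s"][0, :] = 30
        counts["s"][0, 250] = 300
        masks, mean = al.coverage_filter(counts)
        assert not masks["s"][250]
        assert masks["s"].sum() == 499

    def test_all_zero_warns_and_masks_everything(self):
        counts = {"s": np.zeros((6, 100), np.uint32)}
        with pytest.warns(UserWarning):
            masks, mean = al.coverage_filter(counts)
        assert not masks["s"].any()
        assert np.isnan(mean)


class TestSamRoundtrip:
    def test_records_survive_write_read(self, tmp_path):
        genome = Genome([("chr1", random_sequence(5000, seed=19))])
        records = [
            al.AlignmentRecord("q1", "chr1", 100, "+",
                               [("M", 200)], 200, al.UNIQUE, "proper", 3, 200),
            al.AlignmentRecord("q2", "chr1", 900, "-",
                               [("S", 10), ("M", 80), ("D", 4), ("M", 60)],
                               120, al.AMBIGUOUS, "unpaired", 7, 150),
        ]
        path = tmp_path / "out.sam"
        al.write_sam(path, genome, records)
        loaded = al.read_sam(path)
        assert len(loaded) == 2
        for orig, got in zip(records, loaded):
            assert (got.query_id, got.target_id, got.target_start,
                    got.strand, got.cigar, got.nm, got.mapq_proxy,
                    got.score) == (orig.query_id, orig.target_id,
                                   orig.target_start, orig.strand, orig.cigar,
                                   orig.nm, orig.mapq_proxy, orig.score)
        assert loaded[0].pair_state == "proper"
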