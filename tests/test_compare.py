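"""Divergence windows, region flagging, class contrasts, RBH and CDS cover."""

import numpy as np
import pandas as pd
import pytest

from oracles import window_recount

from refscaff import compare as cmp
from refscaff import seqcodec
from refscaff import simulate as sim
from refscaff.errors import FormatError, ParameterError
from refscaff.genome import Genome
from refscaff.variants import ChromosomeClass

from conftest import random_sequence


class TestFragmentGenome:
    def test_piece_lengths_and_order(self):
        g = Genome([("s", random_sequence(25_000, seed=1))])
        pieces = cmp.fragment_genome(g, 10_000)
        assert [p.codes.size for p in pieces] == [10_000, 10_000, 5_000]
        rebuilt = seqcodec.decode(np.concatenate([p.codes for p in pieces]))
        assert rebuilt == g.sequence("s")

    def test_piece_ids_round_trip(self):
        g = Genome([("a", random_sequence(12_000, seed=2)),
                    ("b", random_sequence(4_000, seed=3))])
        for piece in cmp.fragment_genome(g, 5_000):
            scaffold, start, end = cmp.GenomePiece.parse_id(piece.id)
            assert (scaffold, start, end) == (piece.scaffold, piece.start,
                                              piece.end)
            assert np.array_equal(g.codes(scaffold)[start:end], piece.codes)

    def test_nonpositive_piece_rejected(self):
        with pytest.raises(ParameterError):
            cmp.fragment_genome(Genome([("s", "ACGT")]), 0)


class TestPiecewiseDivergence:
    def test_self_comparison_yields_zero_everywhere(self):
        g = Genome([("s", random_sequence(60_000, seed=4))])
        calls = cmp.piecewise_divergence(cmp.fragment_genome(g, 10_000), g)
        assert calls.n_pieces_mapped == calls.n_pieces
        assert sum(int(v.sum()) for v in calls.variable.values()) == 0
        aligned = sum(int(a.sum()) for a in calls.aligned.values())
        assert aligned > 0.99 * 60_000

    def test_overlapping_pieces_excluded(self):
        g = Genome([("s", random_sequence(40_000, seed=5))])
        pieces = cmp.fragment_genome(g, 10_000)
        # plant an extra piece duplicating 5000-15000
        dup = cmp.GenomePiece("s:5000-15000x", "s", 5000, 15_000,
                              g.codes("s")[5000:15_000])
        calls = cmp.piecewise_divergence(pieces + [dup], g)
        assert not calls.aligned["s"][5000:15_000].any()
        assert calls.aligned["s"][:5000].all()

    def test_planted_rate_recovered_within_binomial_noise(self):
        ref = sim.generate_reference(1, [100_000], 0.45, seed=6)
        focal, _ = sim.evolve_genome(ref, 0.05, 0.0, seed=7)
        calls = cmp.piecewise_divergence(cmp.fragment_genome(ref, 10_000),
                                         focal)
        aligned = int(calls.aligned["scaffold_1"].sum())
        variable = int(calls.variable["scaffold_1"].sum())
        sd = np.sqrt(aligned * 0.05 * 0.95)
        assert abs(variable - 0.05 * aligned) < 3 * sd

    def test_draft_n_positions_not_counted(self):
        seq = random_sequence(30_000, seed=8)
        draft = Genome([("s", seq[:10_000] + "N" * 1000 + seq[11_000:])])
        comparator = Genome([("s", seq)])
        calls = cmp.piecewise_divergence(cmp.fragment_genome(comparator, 10_000),
                                         draft)
        assert not calls.aligned["s"][10_000:11_000].any()


class TestWindowDivergence:
    def _calls(self, aligned, variable):
        return cmp.SiteCalls("cmp", {"s": aligned}, {"s": variable})

    def test_simple_ratio(self):
        aligned = np.zeros(50_000, bool)
        aligned[:100] = True
        variable = np.zeros(50_000, bool)
        variable[:5] = True
        win = cmp.window_divergence(self._calls(aligned, variable),
                                    50_000, min_aligned_fraction=0.0)
        assert len(win) == 1
        assert win.iloc[0]["divergence"] == pytest.approx(0.05)

    def test_no_aligned_sites_is_undefined(self):
        win = cmp.window_divergence(
            self._calls(np.zeros(10_000, bool), np.zeros(10_000, bool)), 10_000)
        assert np.isnan(win.iloc[0]["divergence"])

    def test_low_aligned_fraction_marked_undefined(self):
        aligned = np.zeros(10_000, bool)
        aligned[:500] = True  # 5% < 10% floor
        win = cmp.window_divergence(self._calls(aligned, np.zeros(10_000, bool)),
                                    10_000, min_aligned_fraction=0.1)
        assert np.isnan(win.iloc[0]["divergence"])

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        L = 43_000
        aligned = rng.random(L) < 0.8
        variable = aligned & (rng.random(L) < 0.1)
        win = cmp.window_divergence(self._calls(aligned, variable), 10_000,
                                    min_aligned_fraction=0.0)
        expected = window_recount(aligned, variable, 10_000)
        assert list(zip(win["aligned_sites"], win["variable_sites"])) == expected
        assert win.iloc[-1]["end"] == L


class TestFlagDivergent:
    def _windows(self, divergences, scaffold="s", width=50_000):
        return pd.DataFrame([
            {"scaffold": scaffold, "start": i * width, "end": (i + 1) * width,
             "aligned_sites": 1000, "variable_sites": 0,
             "divergence": d, "comparator": "ck"}
            for i, d in enumerate(divergences)])

    def test_cutoff_is_strictly_greater(self):
        regions = cmp.flag_divergent(self._windows([0.15, 0.25, 0.19]), 0.2)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (50_000, 100_000)

    def test_exact_cutoff_not_flagged(self):
        assert cmp.flag_divergent(self._windows([0.2]), 0.2) == []

    def test_all_quiet_no_regions(self):
        assert cmp.flag_divergent(self._windows([0.0, 0.0, 0.0]), 0.2) == []

    def test_adjacent_flagged_windows_merge(self):
        regions = cmp.flag_divergent(self._windows([0.25, 0.3, 0.1, 0.4]), 0.2)
        assert [(r.start, r.end) for r in regions] == [(0, 100_000),
                                                       (150_000, 200_000)]
        assert regions[0].divergence["ck"] == pytest.approx(0.3)

    def test_genes_attached_when_overlapping(self):
        gene_in = cmp.GeneModel("hit", "s", "+", [(60_000, 61_000),
                                                  (63_000, 64_000)])
        gene_out = cmp.GeneModel("miss", "s", "+", [(200_000, 201_000)])
        regions = cmp.flag_divergent(self._windows([0.1, 0.3, 0.1]), 0.2,
                                     [gene_in, gene_out])
        assert regions[0].genes_overlapping == ["hit"]


class TestClassDivergence:
    def _classes(self):
        return [ChromosomeClass("macro", ["chr1"]),
                ChromosomeClass("Z", ["chrZ"])]

    def test_constant_windows_mean_and_sd(self):
        rows = []
        for scaf in ("chr1", "chrZ"):
            for i in range(4):
                rows.append({"scaffold": scaf, "start": i, "end": i + 1,
                             "aligned_sites": 100, "variable_sites": 10,
                             "divergence": 0.1, "comparator": "ck"})
        table, ratio = cmp.class_divergence(pd.DataFrame(rows), self._classes())
        assert np.allclose(table["mean_divergence"], 0.1)
        assert np.allclose(table["sd_divergence"], 0.0)
        assert ratio == pytest.approx(1.0)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for scaf in ("chr1", "chrZ"):
            for i in range(20):
                rows.append({"scaffold": scaf, "start": i, "end": i + 1,
                             "aligned_sites": 100, "variable_sites": 1,
                             "divergence": float(rng.random() * 0.2),
                             "comparator": "ck"})
        windows = pd.DataFrame(rows)
        table, ratio = cmp.class_divergence(windows, self._classes())
        for cls, members in (("macro", ["chr1"]), ("Z", ["chrZ"])):
            vals = [r["divergence"] for r in rows if r["scaffold"] in members]
            row = table[table["class"] == cls].iloc[0]
            assert row["mean_divergence"] == pytest.approx(np.mean(vals))
            assert row["sd_divergence"] == pytest.approx(np.std(vals, ddof=1))
        expected_ratio = (np.mean([r["divergence"] for r in rows
                                   if r["scaffold"] == "chrZ"])
                          / np.mean([r["divergence"] for r in rows
                                     if r["scaffold"] == "chr1"]))
        assert ratio == pytest.approx(expected_ratio)

    def test_faster_z_recovered_from_planted_multiplier(self):
        ref = sim.generate_reference(3, [150_000, 150_000, 150_000], 0.45,
                                     seed=10, names=["chr1", "chr2", "chrZ"],
                                     chrom_classes=["macro", "micro", "Z"])
        focal, _ = sim.evolve_genome(ref, 0.02, 0.0, z_multiplier=1.5, seed=11)
        calls = cmp.piecewise_divergence(cmp.fragment_genome(ref, 10_000), focal)
        windows = cmp.window_divergence(calls, 50_000)
        classes = [ChromosomeClass("macro", ["chr1"]),
                   ChromosomeClass("micro", ["chr2"]),
                   ChromosomeClass("Z", ["chrZ"])]
        _table, ratio = cmp.class_divergence(windows, classes)
        assert abs(ratio - 1.5) / 1.5 < 0.15

    def test_class_without_windows_omitted_with_warning(self):
        windows = pd.DataFrame([{"scaffold": "chr1", "start": 0, "end": 1,
                                 "aligned_sites": 10, "variable_sites": 1,
                                 "divergence": 0.1, "comparator": "ck"}])
        with pytest.warns(UserWarning):
            table, _ = cmp.class_divergence(windows, self._classes())
        assert table["class"].tolist() == ["macro"]


class TestReciprocalBestHits:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["query", "subject", "evalue",
                                           "score"])

    def test_mutual_best_kept(self):
        fwd = self._table([("g1", "r1", 1e-30, 100)])
        rev = self._table([("r1", "g1", 1e-28, 95)])
        pairs = cmp.reciprocal_best_hits(fwd, rev)
        assert len(pairs) == 1
        assert pairs[0].gene_id == "g1" and pairs[0].draft_region == "r1"

    def test_one_way_best_rejected(self):
        fwd = self._table([("g1", "r1", 1e-30, 100)])
        rev = self._table([("r1", "g2", 1e-40, 120), ("r1", "g1", 1e-20, 80)])
        assert cmp.reciprocal_best_hits(fwd, rev) == []

    def test_planted_orthologs_recovered_paralogs_rejected(self):
        fwd_rows, rev_rows = [], []
        for i in range(5):
            fwd_rows.append((f"g{i}", f"r{i}", 1e-50, 200))
            rev_rows.append((f"r{i}", f"g{i}", 1e-45, 190))
        # one-way paralogs: their best forward hit is an ortholog's region
        fwd_rows.append(("p1", "r0", 1e-30, 150))
        fwd_rows.append(("p2", "r3", 1e-25, 140))
        pairs = cmp.reciprocal_best_hits(self._table(fwd_rows),
                                         self._table(rev_rows))
        assert sorted(p.gene_id for p in pairs) == [f"g{i}" for i in range(5)]

    def test_evalue_cutoff_enforced_on_both_sides(self):
        fwd = self._table([("g1", "r1", 1e-8, 100)])
        rev = self._table([("r1", "g1", 1e-50, 95)])
        assert cmp.reciprocal_best_hits(fwd, rev, evalue_cutoff=1e-10) == []

    def test_tie_resolved_by_score_then_id(self):
        fwd = self._table([("g1", "rB", 1e-30, 100), ("g1", "rA", 1e-30, 120)])
        rev = self._table([("rA", "g1", 1e-30, 120)])
        pairs = cmp.reciprocal_best_hits(fwd, rev)
        assert pairs[0].draft_region == "rA"

    def test_malformed_table_rejected(self):
        with pytest.raises(FormatError):
            cmp.reciprocal_best_hits(pd.DataFrame({"query": ["g"]}),
                                     pd.DataFrame({"query": ["r"]}))

    def test_builtin_engine_finds_planted_homologs(self):
        ref = sim.generate_reference(1, [40_000], 0.45, seed=12)
        genes = sim.random_gene_models(ref, 5, seed=13)
        from refscaff.pipeline import gene_span_sequences

        queries = gene_span_sequences(genes, ref)
        hits = cmp.search_hits(queries, ref)
        assert set(hits["query"]) == set(queries)
        best = hits.sort_values(["query", "evalue"]).drop_duplicates("query")
        assert (best["evalue"] < 1e-10).all()


class TestCdsCoverage:
    def test_fully_called_cds(self):
        draft = Genome([("s", random_sequence(5000, seed=14))])
        gene = cmp.GeneModel("g", "s", "+", [(100, 400), (800, 1100)])
        table, hist, over90 = cmp.cds_coverage([gene], draft)
        assert table.iloc[0]["fraction"] == 1.0
        assert over90 == 1

    def test_half_n_cds(self):
        seq = random_sequence(1000, seed=15)
        draft = Genome([("s", seq[:300] + "N" * 200 + seq[500:])])
        gene = cmp.GeneModel("g", "s", "+", [(100, 500)])  # half over N
        table, _, _ = cmp.cds_coverage([gene], draft)
        assert table.iloc[0]["fraction"] == pytest.approx(0.5)

    def test_multi_exon_matches_interval_oracle(self):
        rng = np.random.default_rng(16)
        chars = rng.choice(list("ACGTN"), p=[0.225] * 4 + [0.1], size=4000)
        draft = Genome([("s", "".join(chars))])
        gene = cmp.GeneModel("g", "s", "-", [(50, 350), (700, 900),
                                             (1500, 2100), (3900, 3990)])
        table, _, _ = cmp.cds_coverage([gene], draft)
        expected = sum((np.array(list(draft.sequence("s")[s:e])) != "N").sum()
                       for s, e in gene.cds_intervals) / gene.cds_length
        assert table.iloc[0]["fraction"] == pytest.approx(expected)

    def test_missing_scaffold_flagged_zero(self):
        draft = Genome([("s", "ACGT" * 100)])
        gene = cmp.GeneModel("g", "elsewhere", "+", [(0, 100)])
        table, hist, over90 = cmp.cds_coverage([gene], draft)
        assert table.iloc[0]["fraction"] == 0.0
        assert bool(table.iloc[0]["missing_scaffold"])
        assert over90 == 0

    def test_histogram_bins_sum_to_gene_count(self):
        draft = Genome([("s", random_sequence(2000, seed=17))])
        genes = [cmp.GeneModel(f"g{i}", "s", "+", [(i * 300, i * 300 + 200)])
                 for i in range(5)]
        _, hist, _ = cmp.cds_coverage(genes, draft)
        assert hist.sum() == 5


class TestGff3Roundtrip:
    def test_models_survive_write_read(self, tmp_path):
        genes = [cmp.GeneModel("gene_1", "chr1", "+", [(100, 400), (800, 1000)]),
                 cmp.GeneModel("gene_2", "chr2", "-", [(50, 250)])]
        path = tmp_path / "genes.gff3"
        cmp.write_gene_models(path, genes)
        loaded = cmp.read_gene_models(path)
        assert [(g.gene_id, g.scaffold, g.strand, g.cds_intervals)
                for g in loaded] == [(g.gene_id, g.scaffold, g.strand,
                                      g.cds_intervals) for g in genes]
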