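import numpy as np
import pytest

from csatk.core_io import SeqRecord, revcomp
from csatk.evaluate import (GeneModel, gc_windows, global_identity,
                            classify_differences, map_matepairs,
                            merge_gene_models, read_depth)
from csatk.simulate import random_seq


@pytest.fixture(scope="module")
def base_seq():
    return random_seq(np.random.default_rng(41), 10_000, 0.5)


class TestGlobalIdentity:
    def test_identical_sequences(self, base_seq):
        rep = global_identity(SeqRecord(id="q", seq=base_seq),
                              SeqRecord(id="t", seq=base_seq))
        assert rep.identity == 1.0
        assert len(rep.blocks) == 1
        assert rep.uncovered_query == [] and rep.uncovered_target == []

    def test_27_planted_snps_closed_form(self, base_seq):
        rng = np.random.default_rng(5)
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        t = list(base_seq)
        for p in rng.choice(10_000, size=27, replace=False):
            t[p] = swap[t[p]]
        rep = global_identity(SeqRecord(id="q", seq=base_seq),
                              SeqRecord(id="t", seq="".join(t)))
        assert rep.identity == pytest.approx((10_000 - 27) / 10_000, abs=1e-6)
        assert sum(1 for d in rep.differences if d.type == "SNP") == 27

    def test_unrelated_insertion_reported_uncovered(self, base_seq):
        rng = np.random.default_rng(6)
        insert = random_seq(rng, 500, 0.5)
        q = base_seq[:5000] + insert + base_seq[5000:]
        rep = global_identity(SeqRecord(id="q", seq=q),
                              SeqRecord(id="t", seq=base_seq))
        covered = sum(e - s for s, e, *_ in
                      [(b[0], b[1]) for b in rep.blocks])
        assert covered <= len(q) - 400
        assert any(s <= 5000 < e or (5000 <= s < 5500) for s, e in rep.uncovered_query)

    def test_reverse_orientation_detected(self, base_seq):
        rep = global_identity(SeqRecord(id="q", seq=base_seq),
                              SeqRecord(id="t", seq=revcomp(base_seq)))
        assert rep.orientation == "reverse"
        assert rep.identity == 1.0

    def test_no_anchors_identity_zero(self):
        rng = np.random.default_rng(7)
        rep = global_identity(SeqRecord(id="q", seq=random_seq(rng, 2000, 0.5)),
                              SeqRecord(id="t", seq=random_seq(rng, 2000, 0.5)))
        assert rep.identity == 0.0
        assert rep.uncovered_query == [(0, 2000)]

    def test_symmetric_identity_for_fully_covered(self, base_seq):
        rng = np.random.default_rng(8)
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        t = list(base_seq)
        for p in rng.choice(10_000, size=11, replace=False):
            t[p] = swap[t[p]]
        a = SeqRecord(id="a", seq=base_seq)
        b = SeqRecord(id="b", seq="".join(t))
        assert global_identity(a, b).identity == \
            pytest.approx(global_identity(b, a).identity, abs=1e-9)


class TestClassifyDifferences:
    def _report_for(self, q, t):
        return global_identity(SeqRecord(id="q", seq=q), SeqRecord(id="t", seq=t))

    def test_homopolymer_indel(self, base_seq):
        q = base_seq[:4000] + "GGGGGG" + base_seq[4000:]
        t = base_seq[:4000] + "GGGGG" + base_seq[4000:]
        rep = self._report_for(q, t)
        rep = classify_differences(rep, SeqRecord(id="q", seq=q),
                                   SeqRecord(id="t", seq=t))
        indels = [d for d in rep.differences if d.type == "indel"]
        assert indels and all(d.category == "homopolymer_indel" for d in indels)

    def test_difference_near_gap(self, base_seq):
        q = base_seq[:3000] + "N" * 50 + base_seq[3050:]
        t = list(base_seq)
        t[3060] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[3060]]  # 10 bp from gap
        rep = self._report_for(q, "".join(t))
        rep = classify_differences(rep, SeqRecord(id="q", seq=q),
                                   SeqRecord(id="t", seq="".join(t)))
        near = [d for d in rep.differences if abs(d.q_start - 3060) < 20]
        assert near and near[0].category == "gap"

    def test_normal_snp_at_depth(self, base_seq):
        t = list(base_seq)
        t[5000] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[5000]]
        rep = self._report_for(base_seq, "".join(t))
        depth = np.full(len(base_seq), 100)
        rep = classify_differences(rep, SeqRecord(id="q", seq=base_seq),
                                   SeqRecord(id="t", seq="".join(t)),
                                   query_depth=depth)
        assert [d.category for d in rep.differences] == ["normal"]

    def test_low_coverage_category(self, base_seq):
        t = list(base_seq)
        t[5000] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[5000]]
        rep = self._report_for(base_seq, "".join(t))
        depth = np.full(len(base_seq), 100)
        depth[4900:5100] = 2
        rep = classify_differences(rep, SeqRecord(id="q", seq=base_seq),
                                   SeqRecord(id="t", seq="".join(t)),
                                   query_depth=depth)
        assert [d.category for d in rep.differences] == ["low_coverage"]

    def test_missing_depth_noted(self, base_seq):
        t = list(base_seq)
        t[5000] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[5000]]
        rep = self._report_for(base_seq, "".join(t))
        rep = classify_differences(rep, SeqRecord(id="q", seq=base_seq),
                                   SeqRecord(id="t", seq="".join(t)))
        assert any("low_coverage" in n for n in rep.notes)


def _pairs_from(template, rng, mean, sd, n, read_len=100):
    pairs = []
    for i in range(n):
        ins = int(np.clip(rng.normal(mean, sd), read_len, len(template)))
        s = int(rng.integers(0, len(template) - ins + 1))
        frag = template[s:s + ins]
        pairs.append((SeqRecord(id=f"m{i}/1", seq=frag[:read_len]),
                      SeqRecord(id=f"m{i}/2", seq=revcomp(frag[-read_len:]))))
    return pairs


class TestMapMatepairs:
    def test_intra_scaffold_pairs_concordant(self):
        rng = np.random.default_rng(51)
        scaffold = random_seq(rng, 30_000, 0.5)
        pairs = _pairs_from(scaffold, rng, 2000, 100, 300)
        sup = map_matepairs({2000: pairs}, [SeqRecord(id="s1", seq=scaffold)],
                            {2000: (2000.0, 100.0)})
        assert sup.discordant == 0
        assert sup.concordant > 0.9 * 300  # N-free random seq: nearly all anchor

    def test_bridging_pairs_propose_single_join(self):
        rng = np.random.default_rng(52)
        region = random_seq(rng, 60_000, 0.5)
        s1 = SeqRecord(id="s1", seq=region[:27_000])
        s2 = SeqRecord(id="s2", seq=region[33_000:])
        pairs = _pairs_from(region, rng, 20_000, 2000, 400)
        sup = map_matepairs({20_000: pairs}, [s1, s2], {20_000: (20_000.0, 2000.0)})
        joins = sup.proposed_joins
        assert len(joins) == 1
        assert joins[0].support_count >= 3
        assert {joins[0].scaffold_a, joins[0].scaffold_b} == {"s1", "s2"}
        assert abs(joins[0].implied_gap - 6000) < 3 * 2000

    def test_insufficient_support_listed_not_proposed(self):
        rng = np.random.default_rng(53)
        region = random_seq(rng, 60_000, 0.5)
        s1 = SeqRecord(id="s1", seq=region[:27_000])
        s2 = SeqRecord(id="s2", seq=region[33_000:])
        pairs = _pairs_from(region, rng, 20_000, 2000, 400)
        bridging = []
        kept = 0
        for r1, r2 in pairs:
            in1 = r1.seq in region[:27_000] or revcomp(r1.seq) in region[:27_000]
            in2 = r2.seq in region[33_000:] or revcomp(r2.seq) in region[33_000:]
            if in1 and in2 and kept < 2:
                bridging.append((r1, r2))
                kept += 1
        assert len(bridging) == 2
        sup = map_matepairs({20_000: bridging}, [s1, s2],
                            {20_000: (20_000.0, 2000.0)}, link_min_support=3)
        assert sup.proposed_joins == []
        assert len(sup.links) == 1 and sup.links[0].support_count == 2


class TestReadDepth:
    def test_uniform_coverage_recovered(self):
        rng = np.random.default_rng(54)
        scaffold = random_seq(rng, 5000, 0.5)
        reads = [SeqRecord(id=f"r{i}", seq=scaffold[s:s + 100])
                 for i, s in enumerate(rng.integers(0, 4900, size=2000))]
        depth = read_depth(reads, SeqRecord(id="s", seq=scaffold))
        center = depth[500:4500]
        assert center.mean() == pytest.approx(2000 * 100 / 5000, rel=0.1)


class TestGCWindows:
    def test_single_g_window(self):
        prof = gc_windows("G" * 500)
        assert prof.values == [1.0]

    def test_two_windows_mean(self):
        prof = gc_windows("AT" * 250 + "GC" * 250)
        assert prof.values == [0.0, 1.0]
        assert prof.mean == pytest.approx(0.5)

    def test_all_n_window_skipped_and_counted(self):
        prof = gc_windows("G" * 500 + "N" * 500 + "C" * 500)
        assert prof.skipped == 1
        assert prof.per_window == [1.0, None, 1.0]

    def test_short_sequence_empty(self):
        assert gc_windows("ACGT", window=500).per_window == []

    def test_mean_equals_whole_sequence_gc_when_clean(self):
        rng = np.random.default_rng(55)
        seq = random_seq(rng, 5000, 0.57)
        prof = gc_windows(seq, window=500)
        whole = (seq.count("G") + seq.count("C")) / 5000
        assert prof.mean == pytest.approx(whole, abs=1e-12)


class TestMergeGeneModels:
    def test_homology_precedence(self):
        models = [GeneModel("h1", "s", 100, 2000, 4, "homology", 0.9),
                  GeneModel("d1", "s", 500, 2500, 3, "denovo", 0.8)]
        out = merge_gene_models(models)
        assert [m.id for m in out] == ["h1"]

    def test_80bp_overlap_keeps_both(self):
        models = [GeneModel("a", "s", 0, 1000, 2, "homology", 0.9),
                  GeneModel("b", "s", 920, 2000, 2, "homology", 0.9)]
        assert len(merge_gene_models(models)) == 2

    def test_exactly_100bp_overlap_keeps_both(self):
        models = [GeneModel("a", "s", 0, 1000, 2, "homology", 0.9),
                  GeneModel("b", "s", 900, 2000, 2, "homology", 0.9)]
        assert len(merge_gene_models(models)) == 2  # strict > 100

    def test_denovo_single_exon_dropped(self):
        models = [GeneModel("d1", "s", 0, 1000, 1, "denovo", 0.5)]
        assert merge_gene_models(models) == []

    def test_denovo_low_align_rate_dropped(self):
        models = [GeneModel("d1", "s", 0, 1000, 3, "denovo", 0.2)]
        assert merge_gene_models(models) == []

    def test_denovo_good_support_kept(self):
        models = [GeneModel("d1", "s", 0, 1000, 3, "denovo", 0.5)]
        assert [m.id for m in merge_gene_models(models)] == ["d1"]

    def test_rnaseq_beats_denovo(self):
        models = [GeneModel("r1", "s", 0, 1500, 2, "rnaseq", 0.0),
                  GeneModel("d1", "s", 200, 1400, 5, "denovo", 0.9)]
        assert [m.id for m in merge_gene_models(models)] == ["r1"]
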