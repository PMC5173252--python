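import numpy as np
import pytest

from csatk.core_io import SeqRecord, revcomp
from csatk.csa_merge import (MergeParams, all_pairs_overlaps, build_layout,
                             build_superscaffolds, find_overlap, merge_layout,
                             merge_site_clones, MergedScaffold)
from csatk.simulate import SimConfig, random_seq, simulate_clones, simulate_region


@pytest.fixture(scope="module")
def pieces():
    rng = np.random.default_rng(31)
    return {k: random_seq(rng, n, 0.5)
            for k, n in [("X", 3000), ("Y", 2000), ("Z", 3000), ("W", 2500)]}


class TestFindOverlap:
    def test_exact_dovetail_coordinates(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"] + pieces["Z"])
        e = find_overlap(a, b)
        assert e is not None
        assert (e.a_start, e.a_end, e.b_start, e.b_end) == (3000, 5000, 0, 2000)
        assert e.orientation == "same"
        assert e.aligned_len == 2000 and e.identity == 1.0

    def test_reverse_complement_symmetry(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=revcomp(pieces["Y"] + pieces["Z"]))
        e = find_overlap(a, b)
        assert e is not None and e.orientation == "reverse"
        # same region after flipping back to the plus strand of b
        assert (e.a_start, e.a_end) == (3000, 5000)
        assert (e.b_start, e.b_end) == (3000, 5000)

    def test_absence_is_none(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"])
        b = SeqRecord(id="b", seq=pieces["Z"])
        assert find_overlap(a, b) is None

    def test_planted_snps_listed_and_counted(self, pieces):
        y = list(pieces["Y"])
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        planted = [150, 600, 1000, 1500, 1900]
        for p in planted:
            y[p] = swap[y[p]]
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq="".join(y) + pieces["Z"])
        e = find_overlap(a, b)
        assert e is not None
        snps = [v for v in e.variants if v[1] == "SNP"]
        assert [v[0] for v in snps] == [3000 + p for p in planted]
        assert e.identity == pytest.approx((2000 - 5) / 2000)

    def test_identity_excludes_n_columns(self, pieces):
        y = pieces["Y"]
        a = SeqRecord(id="a", seq=pieces["X"] + y)
        y_gapped = y[:800] + "N" * 100 + y[900:]
        b = SeqRecord(id="b", seq=y_gapped + pieces["Z"])
        e = find_overlap(a, b)
        assert e is not None
        assert e.identity == 1.0  # N columns excluded, rest identical

    def test_min_overlap_threshold(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"][:300])
        b = SeqRecord(id="b", seq=pieces["Y"][:300] + pieces["Z"])
        assert find_overlap(a, b, min_overlap=500) is None
        e = find_overlap(a, b, min_overlap=200)
        assert e is not None and e.aligned_len == 300


class TestBuildLayout:
    def test_three_scaffold_chain(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"] + pieces["Z"])
        c = SeqRecord(id="c", seq=pieces["Z"] + pieces["W"])
        edges = all_pairs_overlaps([a, b, c], MergeParams())
        layouts = build_layout([a, b, c], edges)
        assert len(layouts) == 1
        members = {sid: (off, ori) for sid, off, ori in layouts[0].members}
        assert members["a"] == (0, 1)
        assert members["b"] == (3000, 1)
        assert members["c"] == (5000, 1)

    def test_no_edges_one_layout_each(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"])
        b = SeqRecord(id="b", seq=pieces["Z"])
        layouts = build_layout([a, b], [])
        assert len(layouts) == 2

    def test_simulated_tiling_recovers_order(self):
        cfg = SimConfig(region_len=40_000, seed=13, snp_rate=0.0, indel_rate=0.0,
                        clone_len_min=8000, clone_len_mode=9000, clone_len_max=10_000,
                        clones_per_site=1)
        truth = simulate_region(cfg)
        sites = [(s, s + 600) for s in range(2000, 38_000, 4500)]
        clones = simulate_clones(truth, cfg, sites)
        records = [rec for rec, _m in clones]
        edges = all_pairs_overlaps(records, MergeParams())
        layouts = build_layout(records, edges)
        assert len(layouts) == 1
        recovered = [sid for sid, _o, _r in
                     sorted(layouts[0].members, key=lambda t: t[1])]
        true_order = [m.clone_id for _r, m in
                      sorted(clones, key=lambda cm: cm[1].start)]
        assert recovered == true_order


class TestMergeLayout:
    def test_exact_overlap_length_arithmetic(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"] + pieces["Z"])
        e = find_overlap(a, b)
        layouts = build_layout([a, b], [e])
        m = merge_layout(layouts[0], [a, b])
        assert len(m.seq) == len(a.seq) + len(b.seq) - e.aligned_len

    def test_smaller_gap_wins(self, pieces):
        y = pieces["Y"]
        gap_version = y[:900] + "N" * 100 + y[1000:]
        a = SeqRecord(id="a", seq=pieces["X"] + gap_version)
        b = SeqRecord(id="b", seq=y + pieces["Z"])
        e = find_overlap(a, b)
        assert e is not None
        layouts = build_layout([a, b], [e])
        m = merge_layout(layouts[0], [a, b])
        assert "N" * 100 not in m.seq
        assert y[900:1000] in m.seq
        sources = {src for _s, _e2, src in m.provenance}
        assert "b" in sources

    def test_identical_contributors_deterministic_provenance(self, pieces):
        a = SeqRecord(id="a", seq=pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"])
        e = find_overlap(a, b)
        layouts = build_layout([a, b], [e])
        m = merge_layout(layouts[0], [a, b])
        assert m.seq == pieces["Y"]
        # tie on gaps and length -> lexicographically smaller id
        assert m.provenance == [(0, 2000, "a")]

    def test_provenance_tiles_exactly(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"] + pieces["Z"])
        e = find_overlap(a, b)
        m = merge_layout(build_layout([a, b], [e])[0], [a, b])
        cursor = 0
        for s, end, _src in m.provenance:
            assert s == cursor
            cursor = end
        assert cursor == len(m.seq)

    def test_merge_associative_for_exact_overlaps(self, pieces):
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq=pieces["Y"] + pieces["Z"])
        c = SeqRecord(id="c", seq=pieces["Z"] + pieces["W"])
        params = MergeParams()
        # merge (a+b) then +c
        e_ab = find_overlap(a, b)
        m_ab = merge_layout(build_layout([a, b], [e_ab])[0], [a, b],
                            merged_id="ab")
        r_ab = SeqRecord(id="ab", seq=m_ab.seq)
        e1 = find_overlap(r_ab, c)
        left = merge_layout(build_layout([r_ab, c], [e1])[0], [r_ab, c])
        # merge (b+c) then a+
        e_bc = find_overlap(b, c)
        m_bc = merge_layout(build_layout([b, c], [e_bc])[0], [b, c],
                            merged_id="bc")
        r_bc = SeqRecord(id="bc", seq=m_bc.seq)
        e2 = find_overlap(a, r_bc)
        right = merge_layout(build_layout([a, r_bc], [e2])[0], [a, r_bc])
        assert left.seq == right.seq


class TestSiteAndSuperMerge:
    def test_overlapping_site_clones_one_second_class(self):
        cfg = SimConfig(region_len=30_000, seed=17, snp_rate=0.0, indel_rate=0.0,
                        clone_len_min=12_000, clone_len_mode=14_000,
                        clone_len_max=16_000, clones_per_site=4)
        truth = simulate_region(cfg)
        clones = simulate_clones(truth, cfg, [(14_000, 14_600)])
        by_site = {"s00": [rec for rec, _m in clones]}
        merged, _layouts = merge_site_clones(by_site)
        assert len(merged) == 1
        assert merged[0].cls == "second"

    def test_disjoint_clones_stay_separate(self, pieces):
        by_site = {"s00": [SeqRecord(id="c1", seq=pieces["X"]),
                           SeqRecord(id="c2", seq=pieces["Z"])]}
        merged, _ = merge_site_clones(by_site)
        assert len(merged) == 2

    def test_low_identity_overlap_kept_separate(self, pieces):
        # a dense-variant overlap (2% divergence) must not merge at the
        # default 0.97 identity gate when planted density exceeds it
        rng = np.random.default_rng(23)
        y = list(pieces["Y"])
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for p in rng.choice(2000, size=80, replace=False):  # 4% divergence
            y[p] = swap[y[p]]
        a = SeqRecord(id="a", seq=pieces["X"] + pieces["Y"])
        b = SeqRecord(id="b", seq="".join(y) + pieces["Z"])
        assert find_overlap(a, b, min_identity=0.97) is None
        merged, _ = merge_site_clones({"s": [a, b]})
        assert len(merged) == 2

    def test_superscaffold_count_equals_components(self, pieces):
        second = [
            MergedScaffold(id="m1", seq=pieces["X"] + pieces["Y"], cls="second",
                           provenance=[(0, 5000, "m1")]),
            MergedScaffold(id="m2", seq=pieces["Y"] + pieces["Z"], cls="second",
                           provenance=[(0, 5000, "m2")]),
            MergedScaffold(id="m3", seq=pieces["W"], cls="second",
                           provenance=[(0, 2500, "m3")]),
        ]
        supers, _ = build_superscaffolds(second)
        assert len(supers) == 2
        assert {m.cls for m in supers} == {"super"}
        big = max(supers, key=lambda m: len(m.seq))
        assert len(big.seq) == 8000
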