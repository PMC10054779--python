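"""Read merging, QC screening, OTU clustering, chimeras, enrichment calls."""

import numpy as np
import pandas as pd
import pytest

from lactobin import amplicon
from lactobin.amplicon import (Otu, ScreenParams, Unique, build_count_table,
                               centroid_matcher, cluster_otus, compare_communities,
                               dereplicate, detect_chimera, detect_enriched_otus,
                               merge_read_pair, screen_read, assign_taxonomy)
from lactobin.seqio import CountTable, SampleDesign, SeqRecord, reverse_complement
from lactobin.simulate import mutate_sequence

FWD = "AGAGTTTGATCMTGGCTCAG"
REV = "GWATTACCGCGGCKGCTG"


def q(seq, score=38):
    return [score] * len(seq)


class TestMergeReadPair:
    def test_perfect_four_base_overlap(self):
        fwd = SeqRecord("r", "AAAACCCCGGGG", q("AAAACCCCGGGG"))
        rev = SeqRecord("r", reverse_complement("GGGGTTTT"), q("GGGGTTTT"))
        merged = merge_read_pair(fwd, rev, min_overlap=4)
        assert merged is not None
        assert merged.seq == "AAAACCCCGGGGTTTT"

    def test_no_overlap_returns_none(self):
        fwd = SeqRecord("r", "AAAAAAAA", q("AAAAAAAA"))
        rev = SeqRecord("r", reverse_complement("CCCCCCCC"), q("CCCCCCCC"))
        assert merge_read_pair(fwd, rev, min_overlap=4) is None

    @pytest.mark.parametrize("q_fwd,q_rev,winner", [(20, 38, "rev"), (38, 20, "fwd")])
    def test_higher_quality_base_wins_mismatch(self, q_fwd, q_rev, winner):
        # 10-base overlap with a single mismatch at overlap position 3
        head, ov_f = "TGCATG", "ACGTACGTAC"
        ov_r = "ACGAACGTAC"   # T->A at index 3
        tail = "GGATCC"
        fwd = SeqRecord("r", head + ov_f, [38] * 6 + [38, 38, 38, q_fwd] + [38] * 6)
        rc_rev = ov_r + tail
        rev_seq = reverse_complement(rc_rev)
        rev_quals = list(reversed([38, 38, 38, q_rev] + [38] * 6 + [38] * 6))
        rev = SeqRecord("r", rev_seq, rev_quals)
        merged = merge_read_pair(fwd, rev, min_overlap=8, max_mismatch_frac=0.2)
        assert merged is not None
        expect = "A" if winner == "rev" else "T"
        assert merged.seq[len(head) + 3] == expect
        assert merged.quals[len(head) + 3] == 38

    def test_requires_qualities(self):
        with pytest.raises(ValueError):
            merge_read_pair(SeqRecord("a", "ACGT"), SeqRecord("b", "ACGT", [1] * 4))


def make_amplicon(core_len=410, score=38, rng=None):
    """A merged amplicon with intact resolved primer sites."""
    rng = rng or np.random.default_rng(7)
    fwd_site = FWD.replace("M", "A")
    rev_rc = reverse_complement(REV).replace("M", "C").replace("W", "T").replace("K", "G")
    # resolve degeneracy in the reverse site's complement alphabet directly
    rev_rc = "".join(c if c in "ACGT" else "C" for c in rev_rc)
    core = "".join(rng.choice(list("ACGT"), size=core_len))
    seq = fwd_site + core + rev_rc
    return SeqRecord("amp", seq, [score] * len(seq))


class TestScreenRead:
    @pytest.fixture
    def params(self):
        return ScreenParams(FWD, REV)

    def test_valid_read_passes_and_trims(self, params):
        rec = make_amplicon(core_len=412)     # total 450
        assert len(rec) == 450
        res = screen_read(rec, params)
        assert res.passed
        assert len(res.record) == 450 - len(FWD) - len(REV)

    def test_reverse_oriented_read_passes(self, params):
        res = screen_read(make_amplicon(412).reverse_complement(), params)
        assert res.passed

    def test_length_399_fails(self, params):
        rec = make_amplicon(core_len=399 - len(FWD) - len(REV))
        assert len(rec) == 399
        res = screen_read(rec, params)
        assert (res.passed, res.reason) == (False, "length")

    def test_mean_q_just_below_threshold_fails(self, params):
        rec = make_amplicon(412)
        quals = [33] * 449 + [0]   # mean 32.93, just under Q33
        assert 32.9 < sum(quals) / len(quals) < 33.0
        res = screen_read(SeqRecord(rec.id, rec.seq, quals), params)
        assert (res.passed, res.reason) == (False, "quality")

    def test_broken_primer_fails(self, params):
        rec = make_amplicon(412)
        res = screen_read(SeqRecord(rec.id, "T" + rec.seq[1:], rec.quals), params)
        assert (res.passed, res.reason) == (False, "primer")

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ScreenParams(FWD, REV, min_len=500, max_len=400)


class TestDereplicate:
    def test_counts_conserved(self):
        recs = [(SeqRecord(f"r{i}", "ACGTACGT"), "s1") for i in range(3)]
        recs.append((SeqRecord("r3", "TTTTACGT"), "s1"))
        uni = dereplicate(recs)
        assert sorted(u.total for u in uni.values()) == [1, 3]

    def test_empty_input(self):
        assert dereplicate([]) == {}

    def test_per_sample_counts(self):
        recs = [(SeqRecord("a", "ACGTACGT"), "s1"), (SeqRecord("b", "ACGTACGT"), "s2")]
        (u,) = dereplicate(recs).values()
        assert u.counts == {"s1": 1, "s2": 1}


class TestClusterOtus:
    def test_identical_sequences_one_otu(self):
        uni = dereplicate([(SeqRecord("a", "ACGT" * 30), "s"),
                           (SeqRecord("b", "ACGT" * 30), "s")])
        otus = cluster_otus(uni)
        assert len(otus) == 1 and otus[0].total_count == 2

    @pytest.mark.parametrize("n_diff,n_otus", [(5, 2), (3, 1)])
    def test_radius_boundary_100bp(self, n_diff, n_otus, rng, random_seq):
        base = random_seq(rng, 100)
        other = list(base)
        for i in range(n_diff):
            pos = 10 + 13 * i
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        uni = {base: Unique(base, "a", {"s": 5}),
               "".join(other): Unique("".join(other), "b", {"s": 1})}
        assert len(cluster_otus(uni, radius=0.04)) == n_otus

    def test_empty_input(self):
        assert cluster_otus({}) == []

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            cluster_otus({}, radius=0.6)

    def test_deterministic_and_radius_invariant(self, rng, random_seq):
        base = random_seq(rng, 300)
        seqs = [mutate_sequence(base, 0.97, rng=int(i)) for i in range(15)]
        seqs += [random_seq(rng, 300) for _ in range(5)]
        uni = {s: Unique(s, f"u{i}", {"s": int(rng.integers(1, 20))})
               for i, s in enumerate(seqs)}
        otus1 = cluster_otus(uni, radius=0.04)
        otus2 = cluster_otus(dict(uni), radius=0.04)
        assert [(o.otu_id, o.centroid.seq, o.total_count) for o in otus1] == \
               [(o.otu_id, o.centroid.seq, o.total_count) for o in otus2]
        from lactobin.align import dissimilarity
        for otu in otus1:
            for member in otu.members:
                assert dissimilarity(member, otu.centroid.seq) <= 0.04

    def test_count_conservation(self, rng, random_seq):
        seqs = [random_seq(rng, 200) for _ in range(10)]
        uni = {s: Unique(s, f"u{i}", {"s": i + 1}) for i, s in enumerate(seqs)}
        otus = cluster_otus(uni)
        assert sum(o.total_count for o in otus) == sum(u.total for u in uni.values())


class TestDetectChimera:
    @pytest.fixture
    def parents(self, rng, random_seq):
        a = random_seq(rng, 500)
        b = mutate_sequence(a, 0.90, rng=99)   # 10% divergent
        return SeqRecord("A", a), SeqRecord("B", b)

    def test_constructed_chimera_flagged(self, parents):
        a, b = parents
        query = SeqRecord("q", a.seq[:250] + b.seq[250:])
        assert detect_chimera(query, [a, b]) is True

    def test_exact_parent_copy_not_flagged(self, parents):
        a, b = parents
        assert detect_chimera(SeqRecord("q", a.seq), [a, b]) is False

    def test_noisy_read_not_flagged(self, parents, rng):
        a, b = parents
        noisy = mutate_sequence(a.seq, 0.90, rng=7)
        assert detect_chimera(SeqRecord("q", noisy), [a, b]) is False

    def test_empty_parents_false(self):
        assert detect_chimera(SeqRecord("q", "ACGT" * 50), []) is False


class TestCountTableBuild:
    def test_single_otu(self, small_design):
        otu = Otu("OTU1", SeqRecord("c", "ACGT"), {"ctrl": 10})
        ct = build_count_table([otu], small_design)
        assert ct.counts.loc["OTU1", "ctrl"] == 10
        assert ct.relative().loc["OTU1", "ctrl"] == 1.0

    def test_proportions(self, small_design):
        otus = [Otu("OTU1", SeqRecord("c1", "ACGT"), {"ctrl": 30}),
                Otu("OTU2", SeqRecord("c2", "TTTT"), {"ctrl": 70})]
        rel = build_count_table(otus, small_design).relative()
        assert rel["ctrl"].tolist() == pytest.approx([0.3, 0.7])
        assert rel["ctrl"].sum() == pytest.approx(1.0)

    def test_unknown_sample_named_in_error(self, small_design):
        otu = Otu("OTU1", SeqRecord("c", "ACGT"), {"mystery": 1})
        with pytest.raises(ValueError, match="mystery"):
            build_count_table([otu], small_design)


class TestAssignTaxonomy:
    def test_identical_reference_is_100(self, rng, random_seq):
        s = random_seq(rng, 300)
        otu = Otu("OTU1", SeqRecord("c", s))
        refs = [SeqRecord("refA", s), SeqRecord("refB", random_seq(rng, 300))]
        hit = assign_taxonomy(otu, refs)
        assert (hit.best_ref_id, hit.percent_identity) == ("refA", 100.0)

    def test_single_substitution_20nt(self):
        otu = Otu("OTU1", SeqRecord("c", "ACGTACGTACGTACGTACGT"))
        ref = SeqRecord("ref", "ACGTACGTACGTACGTACGA")
        assert assign_taxonomy(otu, [ref]).percent_identity == 95.0

    def test_empty_reference_set(self):
        with pytest.raises(ValueError):
            assign_taxonomy(Otu("o", SeqRecord("c", "ACGT")), [])


def table_from_relative(rel: dict[str, dict[str, float]], depth=100000) -> CountTable:
    """Integer count table realizing the given per-sample relative abundances."""
    samples = sorted({s for v in rel.values() for s in v})
    feats = sorted(rel)
    data = {}
    for s in samples:
        col = [int(round(rel[f].get(s, 0.0) * depth)) for f in feats]
        col.append(depth - sum(col))   # filler feature absorbs the remainder
        data[s] = col
    return CountTable(pd.DataFrame(data, index=feats + ["other"]))


class TestDetectEnriched:
    @pytest.fixture
    def design(self):
        mk = lambda s, t, r=1: SampleDesign(s, "d1", 14, t, r)  # noqa: E731
        return [mk("ctrl", "control"), mk("s1", "supplemented", 1),
                mk("s2", "supplemented", 2), mk("s3", "supplemented", 3)]

    def test_study_case_donor1(self, design):
        # 7.6% and 33.7% supplemented vs 0.005% control
        ct = table_from_relative({"otu": {"ctrl": 0.00005, "s1": 0.076, "s2": 0.337}})
        design2 = design[:3]
        calls = detect_enriched_otus(ct, design2, day=14)
        call = next(c for c in calls if c.otu_id == "otu")
        assert call.enriched
        assert call.max_fold_change == pytest.approx(6740, rel=1e-3)

    def test_study_case_donor2(self, design):
        # 0.3%, 2.5%, 46.7% supplemented vs 0.05% control
        ct = table_from_relative(
            {"otu": {"ctrl": 0.0005, "s1": 0.003, "s2": 0.025, "s3": 0.467}})
        calls = detect_enriched_otus(ct, design, day=14)
        call = next(c for c in calls if c.otu_id == "otu")
        assert call.enriched
        assert call.max_fold_change == pytest.approx(934, rel=1e-3)

    def test_flat_abundance_not_enriched(self, design):
        ct = table_from_relative(
            {"otu": {"ctrl": 0.1, "s1": 0.1, "s2": 0.1, "s3": 0.1}})
        calls = detect_enriched_otus(ct, design, day=14)
        assert not any(c.enriched for c in calls)

    def test_missing_control_errors(self, design):
        ct = table_from_relative({"otu": {"s1": 0.1}})
        with pytest.raises(ValueError, match="control"):
            detect_enriched_otus(ct, [d for d in design if d.treatment != "control"],
                                 day=14)

    def test_one_low_replicate_blocks_call(self, design):
        # all-replicates rule: a single supplemented replicate at control level
        ct = table_from_relative(
            {"otu": {"ctrl": 0.001, "s1": 0.2, "s2": 0.3, "s3": 0.001}})
        calls = detect_enriched_otus(ct, design, day=14)
        assert not any(c.enriched and c.otu_id == "otu" for c in calls)


class TestCompareCommunities:
    def test_identical_tables_all_shared(self):
        ct = table_from_relative({"x": {"s": 0.9}, "y": {"s": 0.1}}, depth=100)
        cmp = compare_communities(ct, ct)
        assert (cmp.n_shared, cmp.pct_reads_a, cmp.pct_reads_b) == (3, 100.0, 100.0)

    def test_disjoint_centroids_nothing_shared(self, rng, random_seq):
        a = Otu("A1", SeqRecord("a", random_seq(rng, 200)), {"s": 10}, ["x"])
        b = Otu("B1", SeqRecord("b", random_seq(rng, 200)), {"s": 10}, ["x"])
        ta = build_count_table([a], [SampleDesign("s", "d", 14, "control")])
        tb = build_count_table([b], [SampleDesign("s", "d", 14, "control")])
        cmp = compare_communities(ta, tb, centroid_matcher([a], [b]))
        assert (cmp.n_shared, cmp.pct_reads_a, cmp.pct_reads_b) == (0, 0.0, 0.0)

    def test_hand_counted_partition(self):
        ta = CountTable(pd.DataFrame({"s": [90, 10]}, index=["x", "y"]))
        tb = CountTable(pd.DataFrame({"s": [50, 50]}, index=["x", "z"]))
        cmp = compare_communities(ta, tb)
        assert (cmp.n_shared, cmp.pct_reads_a, cmp.pct_reads_b) == (1, 90.0, 50.0)
        assert (cmp.n_unique_a, cmp.n_unique_b) == (1, 1)
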