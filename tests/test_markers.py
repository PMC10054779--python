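"""Ribosomal-protein census, 16S discovery, amplicon extraction, identity."""

import pytest

from lactobin.markers import (default_marker_panel, extract_amplicon_region,
                              find_16s, global_identity,
                              predict_genome_size_range, read_marker_fasta,
                              rprotein_census)
from lactobin.seqio import SeqRecord, reverse_complement
from lactobin.simulate import (make_marker_refs, make_reference_16s,
                               mutate_sequence)


@pytest.fixture(scope="module")
def panel():
    return default_marker_panel()


@pytest.fixture(scope="module")
def marker_refs():
    return make_marker_refs(seed=11)


class TestMarkerPanel:
    def test_panel_size(self, panel):
        assert sum(1 for s in panel.values() if s == "SSU") == 21
        assert sum(1 for s in panel.values() if s == "LSU") == 33

    def test_study_cited_subunits_present(self, panel):
        for name in ("S2p", "L9p", "L20p", "L25p", "L31p", "L35p", "S9p", "L7/L12p"):
            assert name in panel


class TestCensus:
    def test_full_reference_set_all_found(self, panel, marker_refs):
        proteins = [seq for seqs in marker_refs.values() for seq in seqs]
        census = rprotein_census(proteins, marker_refs, panel=panel)
        assert census.ssu_missing == [] and census.lsu_missing == []
        assert len(census.ssu_found) == 21 and len(census.lsu_found) == 33

    def test_empty_bin_all_missing(self, panel, marker_refs):
        census = rprotein_census([], marker_refs, panel=panel)
        assert census.ssu_found == [] and census.lsu_found == []

    def test_planted_s2p_gap_reported_exactly(self, panel, marker_refs):
        proteins = [seq for name, seqs in marker_refs.items() if name != "S2p"
                    for seq in seqs]
        census = rprotein_census(proteins, marker_refs, panel=panel)
        assert census.ssu_missing == ["S2p"]
        assert census.lsu_missing == []

    def test_incomplete_refs_rejected(self, panel, marker_refs):
        partial = {k: v for k, v in marker_refs.items() if k != "S1p"}
        with pytest.raises(ValueError, match="S1p"):
            rprotein_census([], partial, panel=panel)


def test_marker_fasta_round_trip(tmp_path, marker_refs, panel):
    lines = []
    for name, seqs in marker_refs.items():
        for i, seq in enumerate(seqs):
            lines.append(f">m{i}_{name.replace('/', '_')} marker={name} "
                         f"subunit={panel[name]}")
            lines.append(seq)
    p = tmp_path / "markers.faa"
    p.write_text("\n".join(lines) + "\n")
    refs, back_panel = read_marker_fasta(p)
    assert refs == marker_refs
    assert back_panel == panel


@pytest.fixture(scope="module")
def ref():
    return make_reference_16s(seed=2)


class TestFind16s:
    def test_exact_embedding_recovers_coords(self, ref, rng, random_seq):
        contig = SeqRecord("c", random_seq(rng, 100) + ref.seq + random_seq(rng, 3000))
        (hit,) = find_16s([contig], [ref])
        assert (hit.start, hit.end) == (100, 100 + len(ref.seq))
        assert hit.identity_pct == 100.0
        assert hit.length_bp == 1540

    def test_random_contig_no_hit(self, ref, rng, random_seq):
        assert find_16s([SeqRecord("c", random_seq(rng, 5000))], [ref]) == []

    def test_mutated_embedding_identity(self, ref, rng, random_seq):
        mutated = mutate_sequence(ref.seq, 0.95, rng=4)
        contig = SeqRecord("c", random_seq(rng, 200) + mutated + random_seq(rng, 200))
        (hit,) = find_16s([contig], [ref])
        assert hit.identity_pct == pytest.approx(95.0, abs=1.5)

    def test_reverse_strand_detection(self, ref, rng, random_seq):
        contig = SeqRecord("c", random_seq(rng, 150)
                           + reverse_complement(ref.seq) + random_seq(rng, 150))
        (hit,) = find_16s([contig], [ref])
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (150, 150 + len(ref.seq))


class TestExtractAmplicon:
    FWD, REV = "AGAGTTTGATCMTGGCTCAG", "GWATTACCGCGGCKGCTG"

    def test_construction_round_trip(self, rng, random_seq):
        fwd_site = self.FWD.replace("M", "C")
        rev_rc = reverse_complement(self.REV.replace("W", "A").replace("K", "T"))
        core = random_seq(rng, 460)
        template = SeqRecord("t", random_seq(rng, 50) + fwd_site + core + rev_rc
                             + random_seq(rng, 500))
        region = extract_amplicon_region(template, self.FWD, self.REV)
        assert region is not None
        assert region.seq == fwd_site + core + rev_rc

    def test_degenerate_m_matches_a(self):
        template = SeqRecord("t", "CCAMPLATECCC".replace("M", "A").replace("P", "G")
                             .replace("L", "T"))
        region = extract_amplicon_region(template, "AMG", "GGG")
        assert region is not None
        assert region.seq.startswith("AAG") or region.seq.startswith("ACG")

    def test_missing_rev_primer_none(self, rng, random_seq):
        template = SeqRecord("t", self.FWD.replace("M", "A") + random_seq(rng, 400))
        assert extract_amplicon_region(template, self.FWD, self.REV) is None

    def test_ambiguous_template_rejected(self, rng, random_seq):
        site = self.FWD.replace("M", "A")
        template = SeqRecord("t", site + random_seq(rng, 100) + site)
        with pytest.raises(ValueError, match="forward-primer"):
            extract_amplicon_region(template, self.FWD, self.REV)


class TestGlobalIdentity:
    def test_identical(self, rng, random_seq):
        s = random_seq(rng, 300)
        assert global_identity(s, s) == 100.0

    def test_five_substitutions_in_100(self, rng, random_seq):
        a = list(random_seq(rng, 100))
        b = a[:]
        for i in (7, 23, 41, 59, 88):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        assert global_identity("".join(a), "".join(b)) == 95.0

    def test_symmetry(self, rng, random_seq):
        a = random_seq(rng, 250)
        b = mutate_sequence(a, 0.9, rng=3)
        assert global_identity(a, b) == global_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


class TestGenomeSizeRange:
    def test_study_style_range(self):
        sizes = [1_800_000, 1_950_000, 2_000_000, 2_030_000, 2_060_000,
                 2_100_000, 2_140_000, 2_180_000, 2_210_000, 2_240_000,
                 2_270_000]
        assert len(sizes) == 11
        assert predict_genome_size_range(sizes) == (1_800_000, 2_270_000)

    def test_single_value(self):
        assert predict_genome_size_range([5]) == (5, 5)

    def test_order_invariance(self, rng):
        sizes = [int(x) for x in rng.integers(1_000_000, 9_000_000, size=8)]
        shuffled = [sizes[i] for i in rng.permutation(len(sizes))]
        assert predict_genome_size_range(sizes) == predict_genome_size_range(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predict_genome_size_range([])
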