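"""Reference-proteome-guided metagenome contig binning.

Contigs assembled from a mixed community are screened for membership in a
target genome by translating predicted ORFs and aligning them against the
proteome of the target's closest characterized relative (blastp-style local
alignment).  A contig is kept when enough of its predicted proteins are
explained by the reference at the identity/coverage thresholds — 50% amino
acid identity and 70% query coverage were found adequate for relatives at
roughly 89–95% 16S identity.  Gene calling is a deliberate stand-in for an
annotation service: maximal ORFs under the bacterial genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from . import align
from .seqio import SeqRecord, reverse_complement

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_STOPS = frozenset(_TABLE11.stop_codons)          # TAA TAG TGA
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class Cds:
    """A predicted protein-coding sequence on a contig.

    Coordinates are 0-based half-open on the forward strand and include the
    stop codon; ``aa_seq`` excludes the stop and begins with M (start codons
    translate to M regardless of codon).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str

    @property
    def cds_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class ProteinHit:
    query_id: str
    ref_id: str
    aln_len: int
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    min_bp: int
    max_bp: int
    n50_bp: int


@dataclass
class BinResult:
    selected_contig_ids: list[str]
    hits: dict[str, list[ProteinHit]]     # contig -> passing best-hits
    stats: AssemblyStats | None


def filter_shotgun_reads(records: Iterable[SeqRecord], min_len: int = 200) -> list[SeqRecord]:
    """Keep reads of length >= ``min_len`` (inclusive); order preserved."""
    return [r for r in records if len(r) >= min_len]


def translate(codons: str) -> str:
    """Bacterial-code translation; any codon containing a non-ACGT base -> X."""
    aa = []
    for i in range(0, len(codons) - 2, 3):
        codon = codons[i : i + 3]
        if set(codon) <= {"A", "C", "G", "T"}:
            aa.append(_CODON_TO_AA.get(codon, "*"))
        else:
            aa.append("X")
    return "".join(aa)


def call_orfs(contig: SeqRecord, min_aa: int = 30) -> list[Cds]:
    """Maximal ORFs on both strands and all three frames.

    An ORF runs from a start codon (ATG/GTG/TTG) to the nearest in-frame stop;
    within a frame only the longest ORF per stop is reported (the first start
    after the previous stop).  Translation uses genetic code 11 with the start
    codon rendered as M; ORFs without an in-frame stop are not reported.
    """
    bad = set(contig.seq) - _NT
    if bad:
        raise ValueError(f"contig {contig.id}: non-nucleotide characters {sorted(bad)}")
    out: list[Cds] = []
    L = len(contig.seq)
    for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for frame in range(3):
            first_start: int | None = None
            for pos in range(frame, L - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STOPS:
                    if first_start is not None:
                        aa_len = (pos - first_start) // 3
                        if aa_len >= min_aa:
                            s, e = first_start, pos + 3
                            if strand == "-":
                                s, e = L - (pos + 3), L - first_start
                            body = seq[first_start : pos]
                            aa = "M" + translate(body[3:])
                            out.append(Cds(contig.id, s, e, strand, aa))
                    first_start = None
                elif first_start is None and codon in START_CODONS:
                    first_start = pos
    out.sort(key=lambda c: (c.start, c.end, c.strand))
    return out


def align_protein(query_aa: str, ref_aa: str, matrix: str = "BLOSUM62",
                  gap_open: float = 11, gap_extend: float = 1,
                  query_id: str = "query", ref_id: str = "ref") -> ProteinHit | None:
    """Smith–Waterman alignment of a predicted protein against a reference.

    Identity counts identical columns over all aligned columns including
    internal gaps (blastp convention); coverage is aligned columns over the
    *query* length, capped at 100.  Returns None when the optimal local score
    is <= 0.
    """
    la = align.local_protein_align(query_aa, ref_aa, matrix, gap_open, gap_extend)
    if la is None:
        return None
    coverage = min(100.0, 100.0 * la.columns / len(query_aa))
    return ProteinHit(query_id, ref_id, la.columns,
                      la.identity_pct, coverage, la.score)


def best_hit(query: Cds, ref_proteome: Sequence[SeqRecord], **kw) -> ProteinHit | None:
    """Best reference hit for one CDS: highest score, ties to lower ref id."""
    best: ProteinHit | None = None
    for ref in ref_proteome:
        h = align_protein(query.aa_seq, ref.seq, query_id=query.cds_id,
                          ref_id=ref.id, **kw)
        if h is None:
            continue
        if (best is None or h.score > best.score
                or (h.score == best.score and h.ref_id < best.ref_id)):
            best = h
    return best


def screen_contigs(contigs: Sequence[SeqRecord], ref_proteome: Sequence[SeqRecord],
                   id_min_pct: float = 50.0, cov_min_pct: float = 70.0,
                   min_hits: int = 1, min_aa: int = 30) -> BinResult:
    """Select contigs whose predicted proteins match the reference proteome.

    Each contig's ORFs are called and each CDS aligned against every
    reference protein, keeping the best hit per CDS.  A contig is selected
    iff at least ``min_hits`` CDS have best hits passing both the identity
    and coverage thresholds.
    """
    if not ref_proteome:
        raise ValueError("reference proteome is empty")
    selected: list[str] = []
    hits: dict[str, list[ProteinHit]] = {}
    kept: list[SeqRecord] = []
    for contig in contigs:
        passing: list[ProteinHit] = []
        for cds in call_orfs(contig, min_aa=min_aa):
            h = best_hit(cds, ref_proteome)
            if h is not None and h.identity_pct >= id_min_pct and h.coverage_pct >= cov_min_pct:
                passing.append(h)
        if len(passing) >= min_hits:
            selected.append(contig.id)
            hits[contig.id] = passing
            kept.append(contig)
    stats = assembly_stats(kept) if kept else None
    return BinResult(selected, hits, stats)


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Contig-set summary; N50 is the length at which the descending
    cumulative sum first reaches half the total."""
    if not contigs:
        raise ValueError("assembly_stats of an empty contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if acc * 2 >= total:
            n50 = ln
            break
    return AssemblyStats(len(lengths), total, lengths[-1], lengths[0], n50)
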