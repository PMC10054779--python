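"""Pairwise alignment primitives shared across the pipeline.

Three scoring schemes are used, each fixed by the stage that needs it:

* **Global nucleotide** (OTU clustering, taxonomy, identity reporting):
  match +1, mismatch -1, gap -2 (linear), terminal gaps free.  Identity is
  identical columns over aligned columns *including internal gaps* but
  *excluding* terminal-gap overhangs — the convention used when clustering
  equal-locus amplicons.
* **Local protein** (blastp-style contig screen, ribosomal-protein census):
  Smith–Waterman with BLOSUM62 and BLAST-style affine gaps — a gap of
  length k costs ``gap_open + k * gap_extend`` (defaults 11/1).
* **Local nucleotide** (16S discovery in contigs): match +2, mismatch -3,
  gap open 5, extend 2.

All alignments run through Biopython's C ``PairwiseAligner``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTNRYSWKMBDHV")


@lru_cache(maxsize=None)
def _global_nt_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    a.end_gap_score = 0  # terminal gaps free
    return a


@lru_cache(maxsize=None)
def _local_aa_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open for the first gap position; BLAST charges
    # open + extend, hence the shift.
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


@lru_cache(maxsize=None)
def _local_nt_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


@dataclass(frozen=True)
class GlobalAlignment:
    """A trimmed global alignment between two equal-locus sequences."""

    row_a: str          # gapped, terminal overhangs removed
    row_b: str
    identical: int
    columns: int        # aligned columns incl. internal gaps
    lead_a: int         # query positions of `a` skipped in the left overhang
    trail_a: int
    len_a: int
    len_b: int

    # Free terminal gaps exist to forgive small trimming overhangs between
    # equal-locus sequences, but for unrelated pairs the optimal scored
    # alignment degenerates to a few lucky columns (everything else in free
    # end gaps), which would read as ~100% identity.  The identity
    # denominator therefore never drops below 90% of the shorter sequence.
    MIN_COVERAGE = 0.9

    @property
    def identity(self) -> float:
        floor = int(math.ceil(self.MIN_COVERAGE * min(self.len_a, self.len_b)))
        denom = max(self.columns, floor)
        return self.identical / denom if denom else 0.0

    @property
    def dissimilarity(self) -> float:
        return 1.0 - self.identity


def global_align(a: str, b: str, match: float = 1, mismatch: float = -1,
                 gap: float = -2) -> GlobalAlignment:
    """Globally align two sequences with free terminal gaps and trim overhangs."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _global_nt_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    start, end = 0, n
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    ta, tb = row_a[start:end], row_b[start:end]
    identical = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    lead_a = sum(1 for c in row_a[:start] if c != "-")
    trail_a = sum(1 for c in row_a[end:] if c != "-")
    return GlobalAlignment(ta, tb, identical, len(ta), lead_a, trail_a,
                           len(a), len(b))


def global_identity_pct(a: str, b: str) -> float:
    """Percent identity under the global/free-end-gap rule, to 1 decimal."""
    return round(global_align(a, b).identity * 100.0, 1)


def dissimilarity(a: str, b: str) -> float:
    """Clustering distance: 1 - identity (gap columns count as differences)."""
    return global_align(a, b).dissimilarity


@dataclass(frozen=True)
class LocalAlignment:
    row_a: str
    row_b: str
    score: float
    identical: int
    columns: int                 # aligned columns incl. internal gaps
    a_span: tuple[int, int]      # [start, end) on sequence a
    b_span: tuple[int, int]

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identical / self.columns if self.columns else 0.0


def _local_align(aligner: Align.PairwiseAligner, a: str, b: str) -> LocalAlignment | None:
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    blocks_a, blocks_b = aln.aligned
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return LocalAlignment(row_a, row_b, float(score), identical, len(row_a), a_span, b_span)


def local_protein_align(query: str, ref: str, matrix: str = "BLOSUM62",
                        gap_open: float = 11, gap_extend: float = 1) -> LocalAlignment | None:
    """Smith–Waterman protein alignment; None when the optimal score is <= 0."""
    for name, s in (("query", query), ("reference", ref)):
        if not s:
            raise ValueError(f"empty {name} sequence")
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid amino-acid codes in {name}: {sorted(bad)}")
    return _local_align(_local_aa_aligner(matrix, gap_open, gap_extend), query, ref)


def local_nt_align(a: str, b: str, match: float = 2, mismatch: float = -3,
                   gap_open: float = 5, gap_extend: float = 2) -> LocalAlignment | None:
    """Local nucleotide alignment used for rRNA gene discovery."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _local_align(_local_nt_aligner(match, mismatch, gap_open, gap_extend), a, b)


# IUPAC degeneracy: code -> set of concrete bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(primer: str, window: str) -> bool:
    """Exact match of a (possibly degenerate) primer against a concrete window."""
    if len(primer) != len(window):
        return False
    for p, t in zip(primer, window):
        allowed = IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r} in primer")
        if t not in allowed:
            return False
    return True


def find_iupac(primer: str, template: str) -> list[int]:
    """All start offsets where the degenerate primer matches the template."""
    k = len(primer)
    return [
        i for i in range(len(template) - k + 1)
        if iupac_match(primer, template[i : i + k])
    ]
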