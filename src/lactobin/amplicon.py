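"""16S rRNA amplicon processing: merging, QC screening, OTU clustering,
chimera removal, taxonomy and enrichment analysis.

The stages mirror a classic enrichment-culture amplicon workflow: paired
reads are merged on their overlap, screened for intact primers / length /
mean Phred quality, dereplicated, clustered into OTUs by greedy centroid
clustering at a fixed dissimilarity radius (default 4%, suited to the
variable V1–V3 locus), screened for two-parent chimeras, and tabulated per
sample.  Enrichment calls compare supplemented cultures against the
unsupplemented control from the same donor and day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from . import align
from .seqio import CountTable, SampleDesign, SeqRecord, mean_phred, reverse_complement

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Quality-screen thresholds applied to merged amplicons.

    Defaults follow the study design: merged length within [400, 580] bp and
    mean Phred >= Q33.  The primer pair (27F/519R in the study) is required
    configuration — primers are matched exactly under IUPAC degeneracy.
    """

    fwd_primer: str
    rev_primer: str
    min_len: int = 400
    max_len: int = 580
    min_mean_q: float = 33.0

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


@dataclass
class Otu:
    otu_id: str
    centroid: SeqRecord
    member_count_per_sample: dict[str, int] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)   # unique member sequences

    @property
    def total_count(self) -> int:
        return sum(self.member_count_per_sample.values())


@dataclass
class EnrichmentCall:
    otu_id: str
    donor: str
    control_abundance: float
    supplemented_abundances: list[float]
    max_fold_change: float
    enriched: bool


@dataclass
class TaxonomyHit:
    otu_id: str
    best_ref_id: str
    percent_identity: float


def merge_read_pair(fwd: SeqRecord, rev: SeqRecord, min_overlap: int = 20,
                    max_mismatch_frac: float = 0.1) -> SeqRecord | None:
    """Merge a read pair on the longest acceptable 3' overlap.

    The reverse read is reverse-complemented, then the longest overlap of
    length >= ``min_overlap`` whose mismatch fraction is <= the cap is taken.
    In the overlap each consensus base is the higher-quality call and its
    quality the max of the two; on a quality tie the forward base wins.
    Returns None when no acceptable overlap exists.
    """
    if fwd.quals is None or rev.quals is None:
        raise ValueError("merge_read_pair requires qualities on both reads")
    rc = rev.reverse_complement()
    max_ov = min(len(fwd), len(rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        f_tail = fwd.seq[len(fwd) - ov :]
        r_head = rc.seq[:ov]
        mism = sum(1 for a, b in zip(f_tail, r_head) if a != b)
        if mism / ov <= max_mismatch_frac:
            f_q = fwd.quals[len(fwd) - ov :]
            r_q = rc.quals[:ov]
            cons: list[str] = []
            cons_q: list[int] = []
            for a, b, qa, qb in zip(f_tail, r_head, f_q, r_q):
                if a == b:
                    cons.append(a)
                else:
                    cons.append(b if qb > qa else a)
                cons_q.append(max(qa, qb))
            seq = fwd.seq[: len(fwd) - ov] + "".join(cons) + rc.seq[ov:]
            quals = fwd.quals[: len(fwd) - ov] + cons_q + rc.quals[ov:]
            return SeqRecord(fwd.id, seq, quals)
    return None


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reason: str | None          # 'primer' | 'length' | 'quality' | None
    record: SeqRecord | None    # primer-trimmed, fwd-oriented record on pass


def screen_read(merged: SeqRecord, p: ScreenParams) -> ScreenResult:
    """Primer / length / quality screen of a merged amplicon.

    Orientation is fixed by locating the forward primer at the 5' end of
    either strand.  Pass requires the forward primer at the 5' end and the
    reverse complement of the reverse primer at the 3' end (exact IUPAC
    match), merged length within [min_len, max_len], and mean Phred at or
    above the threshold.  On pass, primers are trimmed from the returned
    record.
    """
    fp, rp_rc = p.fwd_primer.upper(), reverse_complement(p.rev_primer.upper())
    oriented = merged
    if not _has_primer_5p(merged.seq, fp):
        flipped = merged.reverse_complement()
        if _has_primer_5p(flipped.seq, fp):
            oriented = flipped
        else:
            return ScreenResult(False, "primer", None)
    if not _has_primer_3p(oriented.seq, rp_rc):
        return ScreenResult(False, "primer", None)
    if not (p.min_len <= len(oriented) <= p.max_len):
        return ScreenResult(False, "length", None)
    if mean_phred(oriented) < p.min_mean_q:
        return ScreenResult(False, "quality", None)
    lo, hi = len(fp), len(oriented) - len(rp_rc)
    quals = None if oriented.quals is None else oriented.quals[lo:hi]
    return ScreenResult(True, None, SeqRecord(oriented.id, oriented.seq[lo:hi], quals))


def _has_primer_5p(seq: str, primer: str) -> bool:
    return len(seq) >= len(primer) and align.iupac_match(primer, seq[: len(primer)])


def _has_primer_3p(seq: str, primer_rc: str) -> bool:
    return len(seq) >= len(primer_rc) and align.iupac_match(primer_rc, seq[-len(primer_rc):])


@dataclass
class Unique:
    """One dereplicated sequence with per-sample counts."""

    seq: str
    rep_id: str                    # id of the first read carrying the sequence
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def dereplicate(records: Iterable[tuple[SeqRecord, str]]) -> dict[str, Unique]:
    """Exact-string dereplication of (record, sample_id) pairs.

    Counts are conserved: the per-sample counts sum to the number of input
    records.
    """
    uniques: dict[str, Unique] = {}
    for rec, sample_id in records:
        u = uniques.get(rec.seq)
        if u is None:
            u = Unique(rec.seq, rec.id)
            uniques[rec.seq] = u
        u.counts[sample_id] = u.counts.get(sample_id, 0) + 1
    return uniques


def cluster_otus(uniques: dict[str, Unique] | Sequence[Unique],
                 radius: float = 0.04) -> list[Otu]:
    """Greedy abundance-ordered centroid clustering (UCLUST-style).

    Uniques are visited in order of total count descending (ties: longer
    sequence first, then lexicographic representative id).  Each unique joins
    the earliest-founded centroid within ``radius`` dissimilarity (global
    alignment, terminal gaps free, gap columns count as differences), else
    founds a new OTU.  Output is ordered by total count descending and is
    deterministic for a given input.
    """
    if not (0 < radius < 0.5):
        raise ValueError("radius must be in (0, 0.5)")
    pool = list(uniques.values()) if isinstance(uniques, dict) else list(uniques)
    pool.sort(key=lambda u: (-u.total, -len(u.seq), u.rep_id))
    otus: list[Otu] = []
    for u in pool:
        home = None
        for otu in otus:
            if align.dissimilarity(u.seq, otu.centroid.seq) <= radius:
                home = otu
                break
        if home is None:
            home = Otu(f"OTU{len(otus) + 1:05d}", SeqRecord(u.rep_id, u.seq))
            otus.append(home)
        home.members.append(u.seq)
        for sample_id, n in u.counts.items():
            home.member_count_per_sample[sample_id] = (
                home.member_count_per_sample.get(sample_id, 0) + n
            )
    otus.sort(key=lambda o: (-o.total_count, o.otu_id))
    for i, otu in enumerate(otus, start=1):
        otu.otu_id = f"OTU{i:05d}"
    return otus


def detect_chimera(query: SeqRecord, parents: Sequence[SeqRecord],
                   min_divergence: float = 0.02, segment_id: float = 0.95) -> bool:
    """Two-parent crossover chimera test.

    For each candidate parent the query is globally aligned once, yielding a
    per-query-position match profile; prefix sums then score every ordered
    parent pair (A left, B right) at every breakpoint in O(1).  The query is
    flagged chimeric iff the best crossover model (with both segments at
    >= ``segment_id`` identity to their parents) beats the best single-parent
    identity by >= ``min_divergence``.  Identities are fractions of the query
    length.  Callers must pass only parents sufficiently more abundant than
    the query (the pipeline uses >= 2x the query count).
    """
    if not parents:
        return False
    L = len(query.seq)
    if L == 0:
        return False
    profiles: list[list[int]] = []  # prefix sums of per-position matches
    for p in parents:
        aln = align.global_align(query.seq, p.seq)
        m = [0] * L
        qpos = aln.lead_a
        for x, y in zip(aln.row_a, aln.row_b):
            if x != "-":
                if x == y:
                    m[qpos] = 1
                qpos += 1
        pref = [0] * (L + 1)
        for i, v in enumerate(m):
            pref[i + 1] = pref[i] + v
        profiles.append(pref)
    best_single = max(pref[L] for pref in profiles) / L
    best_chimera = 0.0
    for ia, pa in enumerate(profiles):
        for ib, pb in enumerate(profiles):
            if ia == ib:
                continue
            for k in range(1, L):
                left = pa[k]
                right = pb[L] - pb[k]
                if left / k < segment_id or right / (L - k) < segment_id:
                    continue
                best_chimera = max(best_chimera, (left + right) / L)
    return best_chimera - best_single >= min_divergence


def remove_chimeras(otus: Sequence[Otu], min_divergence: float = 0.02,
                    segment_id: float = 0.95, parent_ratio: float = 2.0
                    ) -> tuple[list[Otu], list[Otu]]:
    """Screen OTUs against more-abundant centroids; returns (kept, removed)."""
    kept: list[Otu] = []
    removed: list[Otu] = []
    ordered = sorted(otus, key=lambda o: (-o.total_count, o.otu_id))
    for otu in ordered:
        parents = [
            k.centroid for k in kept
            if k.total_count >= parent_ratio * otu.total_count
        ]
        if parents and detect_chimera(otu.centroid, parents,
                                      min_divergence, segment_id):
            removed.append(otu)
        else:
            kept.append(otu)
    return kept, removed


def build_count_table(otus: Sequence[Otu], design: Sequence[SampleDesign]) -> CountTable:
    """OTU-by-sample count table over the design's samples; counts conserved."""
    sample_ids = [d.sample_id for d in design]
    known = set(sample_ids)
    for otu in otus:
        for sid in otu.member_count_per_sample:
            if sid not in known:
                raise ValueError(f"OTU {otu.otu_id} has member from unknown sample {sid!r}")
    data = {
        sid: [otu.member_count_per_sample.get(sid, 0) for otu in otus]
        for sid in sample_ids
    }
    df = pd.DataFrame(data, index=[o.otu_id for o in otus])
    return CountTable(df)


def assign_taxonomy(otu: Otu, ref_16s: Sequence[SeqRecord]) -> TaxonomyHit:
    """Top-hit global percent identity against a reference 16S set.

    A deliberate stand-in for classifier-based taxonomy: the study reports
    results as best-match percent identity, which this reproduces.  Ties are
    broken by lexicographic reference id.
    """
    if not ref_16s:
        raise ValueError("empty 16S reference set")
    best: tuple[float, str] | None = None
    for ref in sorted(ref_16s, key=lambda r: r.id):
        pct = align.global_identity_pct(otu.centroid.seq, ref.seq)
        if best is None or pct > best[0]:
            best = (pct, ref.id)
    return TaxonomyHit(otu.otu_id, best[1], best[0])


def detect_enriched_otus(table: CountTable, design: Sequence[SampleDesign],
                         day: int, min_fold: float = 5.0,
                         pseudo: float = 1e-5) -> list[EnrichmentCall]:
    """Call OTUs enriched in supplemented cultures at ``day``, per donor.

    An OTU is enriched for a donor iff its relative abundance in *every*
    supplemented replicate at ``day`` strictly exceeds the control abundance
    and the max fold change (max supplemented / max(control, pseudo)) is at
    least ``min_fold``.  Calls are sorted by fold change descending.
    """
    rel = table.relative()
    donors = sorted({d.donor for d in design})
    calls: list[EnrichmentCall] = []
    for donor in donors:
        controls = [d.sample_id for d in design
                    if d.donor == donor and d.day == day and d.treatment == "control"]
        supp = [d.sample_id for d in design
                if d.donor == donor and d.day == day and d.treatment == "supplemented"]
        if not controls:
            raise ValueError(f"no control sample for donor {donor!r} at day {day}")
        if not supp:
            continue
        for otu_id in table.feature_ids:
            ctrl = float(rel.loc[otu_id, controls].mean())
            sups = [float(rel.loc[otu_id, s]) for s in supp]
            fold = max(sups) / max(ctrl, pseudo)
            enriched = all(s > ctrl for s in sups) and fold >= min_fold
            calls.append(EnrichmentCall(otu_id, donor, ctrl, sups, fold, enriched))
    calls.sort(key=lambda c: -c.max_fold_change)
    return calls


@dataclass
class CommunityComparison:
    n_shared: int
    pct_reads_a: float
    pct_reads_b: float
    n_unique_a: int
    n_unique_b: int


def centroid_matcher(otus_a: Sequence[Otu], otus_b: Sequence[Otu],
                     radius: float = 0.04) -> Callable[[str, str], bool]:
    """Default feature matcher: centroid dissimilarity <= clustering radius."""
    cen_a = {o.otu_id: o.centroid.seq for o in otus_a}
    cen_b = {o.otu_id: o.centroid.seq for o in otus_b}

    def match(fa: str, fb: str) -> bool:
        return align.dissimilarity(cen_a[fa], cen_b[fb]) <= radius

    return match


def compare_communities(table_a: CountTable, table_b: CountTable,
                        matcher: Callable[[str, str], bool] | None = None
                        ) -> CommunityComparison:
    """Shared/unique OTU partition between two communities (donor Venn).

    ``matcher(feature_a, feature_b)`` declares two OTUs the same feature;
    when None, features match by identical id.  Reported percentages are the
    fraction of each table's total reads carried by its shared OTUs.
    """
    if matcher is None:
        matcher = lambda fa, fb: fa == fb  # noqa: E731
    feats_a, feats_b = table_a.feature_ids, table_b.feature_ids
    shared_a = set()
    shared_b = set()
    for fa in feats_a:
        for fb in feats_b:
            if matcher(fa, fb):
                shared_a.add(fa)
                shared_b.add(fb)
    tot_a = table_a.counts.values.sum()
    tot_b = table_b.counts.values.sum()
    reads_a = table_a.counts.loc[sorted(shared_a)].values.sum() if shared_a else 0
    reads_b = table_b.counts.loc[sorted(shared_b)].values.sum() if shared_b else 0
    return CommunityComparison(
        n_shared=len(shared_a),
        pct_reads_a=100.0 * reads_a / tot_a if tot_a else 0.0,
        pct_reads_b=100.0 * reads_b / tot_b if tot_b else 0.0,
        n_unique_a=len(feats_a) - len(shared_a),
        n_unique_b=len(feats_b) - len(shared_b),
    )
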