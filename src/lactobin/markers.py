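"""Bin validation markers: ribosomal-protein census, 16S discovery,
in-silico amplicon extraction and identity, genome-size prediction.

A genome bin recovered by homology screening is incomplete in unknown ways;
three cheap marker analyses bound how much is missing.  The ribosomal-protein
census counts which of the canonical bacterial r-proteins (21 small-subunit,
33 large-subunit) are encoded in the bin.  16S discovery locates rRNA genes
on contigs by local alignment against reference 16S sequences, and the
extracted amplicon region ties the bin back to the OTU that motivated it.
Genome size is bracketed by the genome sizes of sequenced relatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from . import align
from .align import global_identity_pct  # re-exported: the package-wide identity rule
from .seqio import SeqRecord, reverse_complement

__all__ = [
    "RProteinCensus", "RnaHit", "default_marker_panel", "rprotein_census",
    "find_16s", "extract_amplicon_region", "global_identity",
    "predict_genome_size_range",
]


@dataclass
class RProteinCensus:
    ssu_found: list[str]
    ssu_missing: list[str]
    lsu_found: list[str]
    lsu_missing: list[str]

    @property
    def summary(self) -> str:
        return (f"SSU {len(self.ssu_found)}/{len(self.ssu_found) + len(self.ssu_missing)}, "
                f"LSU {len(self.lsu_found)}/{len(self.lsu_found) + len(self.lsu_missing)}")


@dataclass(frozen=True)
class RnaHit:
    contig_id: str
    start: int
    end: int
    strand: str
    identity_pct: float
    ref_id: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def default_marker_panel() -> dict[str, str]:
    """The 54-marker bacterial r-protein panel: name -> 'SSU'|'LSU'."""
    panel: dict[str, str] = {}
    text = resources.files("lactobin.data").joinpath("marker_panel.tsv").read_text()
    for line in text.splitlines()[1:]:
        name, subunit = line.split("\t")
        panel[name] = subunit
    return panel


def rprotein_census(bin_proteins: Sequence[str],
                    marker_refs: Mapping[str, Sequence[str]],
                    id_min_pct: float = 30.0, cov_min_pct: float = 50.0,
                    panel: Mapping[str, str] | None = None) -> RProteinCensus:
    """Which panel markers have a homolog among the bin's proteins.

    A marker counts as found iff some bin protein aligns to some reference
    sequence of that marker at or above both thresholds.  Coverage here is
    relative to the *reference* (r-proteins are short and conserved, and the
    bin protein may carry fused or mispredicted ends), and thresholds are
    looser than the binning screen for the same reason.
    """
    if panel is None:
        panel = default_marker_panel()
    if not panel:
        raise ValueError("empty marker panel")
    missing_refs = set(panel) - set(marker_refs)
    if missing_refs:
        raise ValueError(f"marker_refs missing panel markers: {sorted(missing_refs)}")
    found: set[str] = set()
    for marker in panel:
        for ref in marker_refs[marker]:
            if marker in found:
                break
            for prot in bin_proteins:
                la = align.local_protein_align(prot, ref)
                if la is None:
                    continue
                cov = min(100.0, 100.0 * la.columns / len(ref))
                if la.identity_pct >= id_min_pct and cov >= cov_min_pct:
                    found.add(marker)
                    break
    def split(subunit: str) -> tuple[list[str], list[str]]:
        names = [m for m, s in panel.items() if s == subunit]
        return ([m for m in names if m in found], [m for m in names if m not in found])

    ssu_found, ssu_missing = split("SSU")
    lsu_found, lsu_missing = split("LSU")
    return RProteinCensus(ssu_found, ssu_missing, lsu_found, lsu_missing)


def find_16s(contigs: Sequence[SeqRecord], ref_16s: Sequence[SeqRecord],
             min_len: int = 1200, id_min_pct: float = 80.0) -> list[RnaHit]:
    """Locate rRNA genes on contigs by local alignment against references.

    Each reference is aligned locally (match +2, mismatch -3, gap 5/2)
    against each contig on both strands; the reported span is the aligned
    contig region.  Overlapping hits on a contig are merged keeping the
    highest-scoring one; only spans >= ``min_len`` at >= ``id_min_pct``
    identity are reported.
    """
    if not ref_16s:
        raise ValueError("empty 16S reference set")
    raw: list[tuple[float, RnaHit]] = []
    for contig in contigs:
        for ref in ref_16s:
            for strand, refseq in (("+", ref.seq), ("-", reverse_complement(ref.seq))):
                la = align.local_nt_align(contig.seq, refseq)
                if la is None:
                    continue
                start, end = la.a_span
                if end - start < min_len or la.identity_pct < id_min_pct:
                    continue
                raw.append((la.score,
                            RnaHit(contig.id, start, end, strand,
                                   round(la.identity_pct, 1), ref.id)))
    raw.sort(key=lambda t: (-t[0], t[1].contig_id, t[1].start))
    hits: list[RnaHit] = []
    for _, h in raw:
        if any(k.contig_id == h.contig_id and k.start < h.end and h.start < k.end
               for k in hits):
            continue
        hits.append(h)
    hits.sort(key=lambda h: (h.contig_id, h.start))
    return hits


def extract_amplicon_region(template: SeqRecord, fwd_primer: str,
                            rev_primer: str) -> SeqRecord | None:
    """In-silico PCR: the region enclosed by the primer pair, primers included.

    Primers are matched exactly under IUPAC degeneracy; the reverse primer is
    searched as its reverse complement downstream of the forward site.
    Returns None when either primer is absent; multiple forward-primer sites
    make the template ambiguous and raise.
    """
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer.upper())
    fwd_sites = align.find_iupac(fwd, template.seq)
    if len(fwd_sites) > 1:
        raise ValueError(f"template {template.id}: {len(fwd_sites)} forward-primer sites")
    if not fwd_sites:
        return None
    start = fwd_sites[0]
    rev_sites = [p for p in align.find_iupac(rev_rc, template.seq)
                 if p >= start + len(fwd)]
    if not rev_sites:
        return None
    end = rev_sites[0] + len(rev_rc)
    return SeqRecord(f"{template.id}:{start}-{end}", template.seq[start:end])


def global_identity(a: SeqRecord | str, b: SeqRecord | str) -> float:
    """Percent identity under the global free-end-gap rule, to 1 decimal."""
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("cannot compute identity of an empty sequence")
    return global_identity_pct(sa, sb)


def read_marker_fasta(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Read marker references from FASTA with ``marker=<name> subunit=<SSU|LSU>``
    header tags; returns (marker -> sequences, marker -> subunit)."""
    refs: dict[str, list[str]] = {}
    panel: dict[str, str] = {}
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tags = dict(t.split("=", 1) for t in header.split()[1:] if "=" in t)
        if "marker" not in tags or "subunit" not in tags:
            raise ValueError(f"marker FASTA header lacks marker=/subunit= tags: {header!r}")
        refs.setdefault(tags["marker"], []).append("".join(chunks).upper())
        panel.setdefault(tags["marker"], tags["subunit"])

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            elif line:
                chunks.append(line.strip())
    flush()
    return refs, panel


def predict_genome_size_range(related_sizes_bp: Sequence[int]) -> tuple[int, int]:
    """Bracket a genome size by the min/max of sequenced relatives' sizes."""
    if not related_sizes_bp:
        raise ValueError("no related genome sizes supplied")
    return (min(related_sizes_bp), max(related_sizes_bp))
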