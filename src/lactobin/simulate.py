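"""Synthetic data generators with planted truth for every pipeline stage.

The generators emulate the study's structure at desk scale: enrichment
cultures in which one planted taxon responds to substrate supplementation,
V1–V3 amplicon read pairs with primer sites, Phred qualities, substitution
errors and two-parent chimeras, and a mixed metagenome whose target-genome
contigs carry proteins at a controlled amino-acid identity to a reference
proteome, with ribosomal-protein genes and one 16S gene embedded verbatim.

Every generator is deterministic given its seed.  Design choices that keep
the truth exact are documented in the methods note: sample noise factors are
truncated at three sigma so an enrichment fold larger than the worst-case
noise ratio *guarantees* higher relative abundance in supplemented samples,
and intergenic spacers are built from a stop-codon-saturated repeat so that
ORF calls start exactly at planted gene starts.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SampleDesign, SeqRecord, reverse_complement
from .markers import default_marker_panel

log = logging.getLogger(__name__)

# Concrete binding-site realizations of the degenerate V1-V3 primer pair.
DEFAULT_FWD_PRIMER = "AGAGTTTGATCMTGGCTCAG"   # 27F
DEFAULT_REV_PRIMER = "GWATTACCGCGGCKGCTG"     # 519R

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# All three frames on both strands of this repeat contain a stop codon, and
# it contains no start codon: spacers built from it terminate ORFs cleanly.
_SPACER_UNIT = "TTAATTAATTAA"

_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT

for _codon, _aa in _CT.unambiguous_dna_by_id[11].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A named substream of the run seed; stable across runs and platforms."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=n - 1))


def mutate_sequence(seq: str, target_identity: float,
                    alphabet: str | None = None,
                    rng: np.random.Generator | int | None = None) -> str:
    """Substitute positions i.i.d. so expected identity equals the target.

    Each position mutates with probability ``1 - target_identity``; the
    replacement is uniform over the alphabet minus the original character.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if alphabet is None:
        alphabet = "ACGT" if set(seq) <= set("ACGTN") else AA20
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < 1 - target_identity)
    for i in hits:
        choices = alphabet.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Community / amplicon simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunitySpec:
    """A culture-series community with one planted enrichment response."""

    n_taxa: int = 20
    seed: int = 0
    sigma: float = 1.5            # lognormal spread of baseline abundances
    noise_sigma: float = 0.3      # per-sample abundance noise (truncated 3 sigma)
    target_taxon: str | None = "taxon001"   # None = no enrichment
    fold: float = 100.0
    enrich_day: int = 14
    amplicon_core_len: int = 450
    taxon_divergence: float = 0.10  # per-taxon mutation load from the base 16S

    def __post_init__(self) -> None:
        if self.target_taxon is not None:
            if self.fold <= 1:
                raise ValueError("enrichment fold must be > 1")
            if self.n_taxa < 2:
                raise ValueError("enrichment plan requires n_taxa >= 2")


def default_design(donors: Sequence[str] = ("donor1",),
                   n_supplemented: int = 3,
                   days: Sequence[int] = (7, 14)) -> list[SampleDesign]:
    """The study's culture layout: per donor and day, one unsupplemented
    control plus lactate-supplemented replicate cultures."""
    design: list[SampleDesign] = []
    for donor in donors:
        for day in days:
            design.append(SampleDesign(f"{donor}_d{day}_ctrl", donor, day, "control"))
            for r in range(1, n_supplemented + 1):
                design.append(SampleDesign(f"{donor}_d{day}_lac{r}", donor, day,
                                           "supplemented", r))
    return design


def make_community_templates(spec: CommunitySpec) -> dict[str, SeqRecord]:
    """Per-taxon V1-V3 amplicon templates (primer sites included).

    Taxa diverge independently from a common random core, so pairwise
    dissimilarity (~2x the per-taxon load) far exceeds the 4% OTU radius.
    """
    rng = stage_rng(spec.seed, "templates")
    fwd_site = _resolve_iupac(DEFAULT_FWD_PRIMER, rng)
    rev_site_rc = reverse_complement(_resolve_iupac(DEFAULT_REV_PRIMER, rng))
    base = random_dna(rng, spec.amplicon_core_len)
    out: dict[str, SeqRecord] = {}
    for i in range(spec.n_taxa):
        name = f"taxon{i + 1:03d}"
        core = mutate_sequence(base, 1 - spec.taxon_divergence, rng=rng)
        out[name] = SeqRecord(name, fwd_site + core + rev_site_rc)
    return out


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    from .align import IUPAC

    return "".join(c if c in "ACGT" else IUPAC[c][rng.integers(len(IUPAC[c]))]
                   for c in primer.upper())


def simulate_community(spec: CommunitySpec,
                       design: Sequence[SampleDesign] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Relative-abundance table (taxa x samples) with planted truth.

    Supplemented samples at the enrichment day multiply the target taxon's
    weight by ``fold`` before renormalization.  Noise factors are truncated
    lognormals, so the target's relative abundance in every supplemented
    sample strictly exceeds the control whenever
    ``fold > exp(6 * noise_sigma)``.
    """
    if design is None:
        design = default_design()
    rng = stage_rng(spec.seed, "community")
    taxa = [f"taxon{i + 1:03d}" for i in range(spec.n_taxa)]
    donors = sorted({d.donor for d in design})
    base: dict[str, np.ndarray] = {}
    for donor in donors:
        w = np.exp(rng.normal(0.0, spec.sigma, spec.n_taxa))
        if spec.target_taxon is not None:
            # the planted responder is a rare resident at baseline, as in the
            # study's cultures (control abundances of 0.005-0.05%)
            w[taxa.index(spec.target_taxon)] = w.min() * 0.5
        base[donor] = w
    cols: dict[str, np.ndarray] = {}
    for d in design:
        noise = np.exp(np.clip(rng.normal(0.0, spec.noise_sigma, spec.n_taxa),
                               -3 * spec.noise_sigma, 3 * spec.noise_sigma))
        w = base[d.donor] * noise
        if (spec.target_taxon is not None and d.treatment == "supplemented"
                and d.day == spec.enrich_day):
            w[taxa.index(spec.target_taxon)] *= spec.fold
        cols[d.sample_id] = w / w.sum()
    table = pd.DataFrame(cols, index=taxa)
    truth = {"target_taxon": spec.target_taxon, "fold": spec.fold,
             "enrich_day": spec.enrich_day}
    return table, truth


@dataclass
class ReadTruth:
    read_id: str
    sample_id: str
    taxon: str
    chimera: bool
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None


def simulate_amplicon_reads(abundances: pd.DataFrame,
                            templates: Mapping[str, SeqRecord],
                            n_reads: int = 500,
                            read_len: int = 300,
                            sub_error_rate: float = 0.003,
                            chimera_rate: float = 0.0,
                            seed: int = 0,
                            q_good: int = 38, q_bad: int = 12
                            ) -> tuple[dict[str, list[tuple[SeqRecord, SeqRecord]]],
                                       list[ReadTruth]]:
    """Paired amplicon reads per sample, with per-read truth labels.

    Template molecules are drawn multinomially by abundance; a
    ``chimera_rate`` fraction are replaced by two-parent single-breakpoint
    crossovers (breakpoint uniform in the middle 20–80% of the template).
    Reads cover the two amplicon ends; substitution errors are i.i.d. with
    quality ``q_bad`` at planted errors and ``q_good`` elsewhere, so the
    mean-quality filter is exercised by the error mix.
    """
    if not (0 <= sub_error_rate < 1 and 0 <= chimera_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taxa = list(abundances.index)
    pairs: dict[str, list[tuple[SeqRecord, SeqRecord]]] = {}
    truth: list[ReadTruth] = []
    for sample in abundances.columns:
        probs = abundances[sample].to_numpy(dtype=float)
        probs = probs / probs.sum()
        counts = rng.multinomial(n_reads, probs)
        out: list[tuple[SeqRecord, SeqRecord]] = []
        i = 0
        for taxon, k in zip(taxa, counts):
            for _ in range(k):
                rid = f"{sample}_r{i:06d}"
                i += 1
                tmpl = templates[taxon].seq
                rt = ReadTruth(rid, sample, taxon, False)
                if chimera_rate and rng.random() < chimera_rate:
                    other = taxa[rng.integers(len(taxa))]
                    while other == taxon:
                        other = taxa[rng.integers(len(taxa))]
                    b = templates[other].seq
                    lo, hi = int(0.2 * len(tmpl)), int(0.8 * len(tmpl))
                    bp = int(rng.integers(lo, hi))
                    tmpl = tmpl[:bp] + b[bp:]
                    rt = ReadTruth(rid, sample, taxon, True, taxon, other, bp)
                fwd = _read_with_errors(rid, tmpl[:read_len], rng,
                                        sub_error_rate, q_good, q_bad)
                rev = _read_with_errors(rid, reverse_complement(tmpl)[:read_len],
                                        rng, sub_error_rate, q_good, q_bad)
                out.append((fwd, rev))
                truth.append(rt)
        pairs[sample] = out
    return pairs, truth


def _read_with_errors(rid: str, seq: str, rng: np.random.Generator,
                      rate: float, q_good: int, q_bad: int) -> SeqRecord:
    bases = list(seq)
    quals = [q_good] * len(bases)
    if rate > 0:
        for i in np.flatnonzero(rng.random(len(bases)) < rate):
            choices = "ACGT".replace(bases[i], "")
            bases[i] = choices[rng.integers(3)]
            quals[i] = q_bad
    return SeqRecord(rid, "".join(bases), quals)


# ---------------------------------------------------------------------------
# Metagenome simulation
# ---------------------------------------------------------------------------

@dataclass
class MetagenomeSpec:
    """A mixed metagenome with one target genome at controlled aa identity."""

    ref_proteome: Sequence[SeqRecord] = ()
    target_identity: float = 0.60
    off_target_identity: float = 0.25
    n_off_target_genomes: int = 1
    contig_min_bp: int = 2000
    contig_max_bp: int = 8000
    embedded_markers: Mapping[str, str] = field(default_factory=dict)
    ref_16s: SeqRecord | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for x in (self.target_identity, self.off_target_identity):
            if not (0 < x <= 1):
                raise ValueError("identities must be in (0, 1]")


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice; the first residue gets ATG."""
    codons = ["ATG"]
    for res in aa[1:]:
        opts = _CODONS_BY_AA.get(res)
        if opts is None:
            raise ValueError(f"cannot back-translate residue {res!r}")
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _spacer(rng: np.random.Generator, min_len: int = 36, max_len: int = 120) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return (_SPACER_UNIT * (n // len(_SPACER_UNIT) + 2))[:n]


def _pseudo_genome(proteins: Sequence[SeqRecord], identity: float,
                   rng: np.random.Generator) -> str:
    parts: list[str] = []
    for prot in proteins:
        aa = prot.seq
        if identity < 1:
            aa = "M" + mutate_sequence(aa[1:] if aa.startswith("M") else aa,
                                       identity, AA20, rng)
        elif not aa.startswith("M"):
            aa = "M" + aa
        parts.append(_spacer(rng))
        parts.append(back_translate(aa, rng) + "TAA")
    parts.append(_spacer(rng))
    return "".join(parts)


def _fragment(genome: str, prefix: str, rng: np.random.Generator,
              min_bp: int, max_bp: int, start_index: int = 1) -> list[SeqRecord]:
    contigs: list[SeqRecord] = []
    pos, i = 0, start_index
    while pos < len(genome):
        n = int(rng.integers(min_bp, max_bp + 1))
        chunk = genome[pos : pos + n]
        if len(chunk) >= 200:   # drop sub-read-length tail fragments
            contigs.append(SeqRecord(f"{prefix}{i:04d}", chunk))
            i += 1
        pos += n
    return contigs


@dataclass
class MetagenomeTruth:
    labels: pd.DataFrame                  # contig_id -> label (target/off_target)
    rrna_contig: str | None               # contig carrying the embedded 16S
    rrna_span: tuple[int, int] | None     # [start, end) on that contig
    marker_names: list[str]


def simulate_metagenome(spec: MetagenomeSpec) -> tuple[list[SeqRecord], MetagenomeTruth]:
    """Contig set plus truth table for the binning/census/16S stages.

    The target pseudo-genome back-translates every reference protein after
    mutating it to the target amino-acid identity; chosen ribosomal-protein
    genes and one 16S gene are embedded verbatim.  Off-target genomes are
    built the same way at their own identity and fragmented identically.
    """
    if len(spec.ref_proteome) == 0:
        raise ValueError("reference proteome is empty")
    if spec.off_target_identity >= spec.target_identity:
        log.warning("off-target identity %.2f >= target identity %.2f: "
                    "the identity axis will not separate the genomes",
                    spec.off_target_identity, spec.target_identity)
    rng = stage_rng(spec.seed, "metagenome")
    genome = _pseudo_genome(spec.ref_proteome, spec.target_identity, rng)
    contigs = _fragment(genome, "target_", rng, spec.contig_min_bp, spec.contig_max_bp)

    marker_names = sorted(spec.embedded_markers)
    if marker_names:
        marker_genome = "".join(
            _spacer(rng) + back_translate(spec.embedded_markers[m], rng) + "TAA"
            for m in marker_names
        ) + _spacer(rng)
        contigs.extend(_fragment(marker_genome, "target_m", rng,
                                 spec.contig_min_bp, spec.contig_max_bp))

    rrna_contig = rrna_span = None
    if spec.ref_16s is not None:
        # the rRNA gene sits among ordinary protein genes, as on a real contig
        left = _pseudo_genome(spec.ref_proteome[:2], spec.target_identity, rng)
        right = _pseudo_genome(spec.ref_proteome[2:4], spec.target_identity, rng)
        seq = left + spec.ref_16s.seq + right
        rrna_contig = "target_rrna1"
        rrna_span = (len(left), len(left) + len(spec.ref_16s.seq))
        contigs.append(SeqRecord(rrna_contig, seq))

    labels = [(c.id, "target") for c in contigs]
    for g in range(spec.n_off_target_genomes):
        off = _pseudo_genome(spec.ref_proteome, spec.off_target_identity, rng)
        off_contigs = _fragment(off, f"off{g + 1}_", rng,
                                spec.contig_min_bp, spec.contig_max_bp)
        contigs.extend(off_contigs)
        labels.extend((c.id, "off_target") for c in off_contigs)

    truth = MetagenomeTruth(
        labels=pd.DataFrame(labels, columns=["contig_id", "label"]).set_index("contig_id"),
        rrna_contig=rrna_contig,
        rrna_span=rrna_span,
        marker_names=marker_names,
    )
    return contigs, truth


def make_reference_proteome(n_proteins: int = 50, mean_len: int = 120,
                            seed: int = 0) -> list[SeqRecord]:
    """Random reference proteome; lengths vary +/-40% around the mean."""
    rng = stage_rng(seed, "ref_proteome")
    lo, hi = max(35, int(0.6 * mean_len)), int(1.4 * mean_len)
    return [SeqRecord(f"ref{i + 1:04d}", random_protein(rng, int(rng.integers(lo, hi + 1))))
            for i in range(n_proteins)]


def make_marker_refs(seed: int = 0, panel: Mapping[str, str] | None = None,
                     min_len: int = 90, max_len: int = 180) -> dict[str, list[str]]:
    """Synthetic reference sequences for the 54-marker r-protein panel."""
    if panel is None:
        panel = default_marker_panel()
    rng = stage_rng(seed, "marker_refs")
    return {name: [random_protein(rng, int(rng.integers(min_len, max_len + 1)))]
            for name in panel}


def make_reference_16s(seed: int = 0, length: int = 1540) -> SeqRecord:
    """A synthetic full-length 16S stand-in carrying the V1-V3 primer sites."""
    rng = stage_rng(seed, "ref_16s")
    fwd = _resolve_iupac(DEFAULT_FWD_PRIMER, rng)
    rev_rc = reverse_complement(_resolve_iupac(DEFAULT_REV_PRIMER, rng))
    lead = random_dna(rng, 30)
    core = random_dna(rng, 450)
    tail_len = length - len(lead) - len(fwd) - len(core) - len(rev_rc)
    tail = random_dna(rng, max(tail_len, 0))
    return SeqRecord(f"syn16S_{seed}", lead + fwd + core + rev_rc + tail)
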