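"""Sequence records, sample designs, count tables and FASTA/FASTQ I/O.

Every stage of the pipeline shares the same minimal record type: an id, an
uppercase sequence string, and (for reads) per-base Phred scores.  Quality
encoding is fixed to Phred+33 — the modern Illumina convention — and is not
auto-detected.  Coordinates throughout the package are 0-based, half-open
``[start, end)`` with strand encoded as ``'+'``/``'-'``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

PHRED_OFFSET = 33


class ParseError(ValueError):
    """Raised when a FASTA/FASTQ/TSV input is malformed."""


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities.

    ``quals``, when present, must have one integer score per base.
    """

    id: str
    seq: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = self.seq.upper().replace("U", "T")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality scores "
                f"for {len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        quals = None if self.quals is None else list(reversed(self.quals))
        return SeqRecord(self.id, self.seq.translate(_COMPLEMENT)[::-1], quals)


@dataclass(frozen=True)
class SampleDesign:
    """One sample's position in the culture experiment.

    donor/day/treatment/replicate jointly identify the sample; ``day`` is the
    culture day (0 = inoculum; the study sampled days 7 and 14) and treatment
    is ``"control"`` or ``"supplemented"`` (lactate added).
    """

    sample_id: str
    donor: str
    day: int
    treatment: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "supplemented"):
            raise ValueError(f"unknown treatment {self.treatment!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mean_phred(record: SeqRecord) -> float:
    """Arithmetic mean of the per-base Phred scores."""
    if record.quals is None:
        raise ValueError(f"record {record.id!r} has no quality scores")
    if not record.quals:
        raise ValueError(f"record {record.id!r} is empty")
    return sum(record.quals) / len(record.quals)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Yield records from a 4-line-per-record, Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: record {header[1:]!r} missing '+' line")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {header[1:]!r} sequence/quality length mismatch"
                )
            rec_id = header[1:].split()[0]
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            if any(q < 0 for q in quals):
                raise ParseError(
                    f"{path}: record {rec_id!r} has quality below '!' "
                    "(is this Phred+33?)"
                )
            yield SeqRecord(rec_id, seq, quals)


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; the record id is the header token before whitespace."""
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence under header {header!r}")
        records.append(SeqRecord(header.split()[0], seq))

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line:
                if header is None:
                    raise ParseError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor": str})
    required = {"sample_id", "donor", "day", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: design table missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return [
        SampleDesign(
            sample_id=str(r.sample_id),
            donor=str(r.donor),
            day=int(r.day),
            treatment=str(r.treatment),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "donor": d.donor,
                "day": d.day,
                "treatment": d.treatment,
                "replicate": d.replicate,
            }
            for d in design
        ]
    ).to_csv(path, sep="\t", index=False)


class CountTable:
    """Feature-by-sample table of non-negative integer read counts.

    Wraps a pandas DataFrame (rows = feature/OTU ids, columns = sample ids).
    Relative abundances are derived per column; an all-zero column stays zero.
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not (counts.values == counts.values.astype(int)).all():
            raise ValueError("counts must be integers")
        self.counts = counts.astype(int)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances; columns sum to 1 (or stay 0)."""
        totals = self.counts.sum(axis=0)
        rel = self.counts.div(totals.where(totals > 0, 1), axis=1)
        return rel.astype(float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.counts.equals(other.counts)
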