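"""Sequence I/O for carrier-sequencing runs.

Reads and writes plain or gzipped FASTA/FASTQ (4-line, Phred+33) and
extracts the flowcell channel from read IDs of the form
``channel_<N>_<uuid>_template`` as emitted by MinKNOW-era basecallers.
Parsing itself is delegated to Biopython; this module adds the domain
types and the channel-attribution logic the downstream pipeline needs.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "GenomeSequence",
    "ReadRecord",
    "parse_read_id",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
]

#: Canonical read-ID layout: channel number, a token (usually a UUID), and
#: the 1D "template" suffix.  A leading "@" is tolerated and stripped.
_READ_ID_RE = re.compile(r"^@?channel_(\d+)_(.+)_template$")


@dataclass(frozen=True)
class GenomeSequence:
    """A reference genome (or genome stand-in) as a plain uppercase string."""

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_count(self) -> int:
        """Number of ambiguous (N) bases tolerated by the parser."""
        return self.bases.count("N")


@dataclass(frozen=True)
class ReadRecord:
    """One basecalled read with its flowcell-channel attribution.

    ``channel`` and ``uuid`` are ``None`` when the read ID does not follow
    the ``channel_<N>_<uuid>_template`` layout; such reads still flow
    through the carrier and QC filters but are excluded from the
    per-channel noise test (they cannot be attributed to a pore).
    """

    read_id: str
    bases: str
    quality: str
    channel: int | None = None
    uuid: str | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and quality "
                f"({len(self.quality)}) lengths differ"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_strings(cls, read_id: str, bases: str, quality: str) -> "ReadRecord":
        channel, uuid = parse_read_id(read_id)
        return cls(read_id.lstrip("@"), bases, quality, channel, uuid)


def parse_read_id(read_id: str) -> tuple[int | None, str | None]:
    """Extract (channel, uuid) from a ``channel_<N>_<uuid>_template`` ID.

    Non-conforming IDs degrade gracefully to ``(None, None)`` rather than
    raising: metadata parsing fails open, the channel statistics downstream
    fail closed.
    """
    m = _READ_ID_RE.match(read_id.strip())
    if m is None:
        return None, None
    return int(m.group(1)), m.group(2)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a 4-line FASTQ file (optionally gzipped) into ReadRecords.

    A record whose quality string length disagrees with its sequence is a
    hard error naming the (1-based) record index; channel attribution is
    attempted on every ID and never fails.
    """
    records: list[ReadRecord] = []
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record {index + 1} in {path}: {exc}"
                ) from exc
            index += 1
            read_id = title.split()[0] if title.split() else title
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {index} in {path}: sequence and "
                    f"quality lengths differ ({len(seq)} vs {len(qual)})"
                )
            records.append(ReadRecord.from_strings(read_id, seq.upper(), qual))
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records as 4-line Phred+33 FASTQ, restoring the leading "@"."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.bases}\n+\n{rec.quality}\n")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse a multi-record FASTA, case-folding bodies to uppercase."""
    genomes: list[GenomeSequence] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            bases = str(rec.seq).upper()
            if not bases:
                raise ValueError(f"FASTA record {rec.id!r} in {path} has an empty body")
            genomes.append(GenomeSequence(rec.id, bases))
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for g in genomes:
            handle.write(f">{g.id}\n")
            for i in range(0, len(g.bases), width):
                handle.write(g.bases[i : i + width] + "\n")
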