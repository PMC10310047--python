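"""Protein FASTA databases: reading, writing, and organism extraction.

Records keep their description line byte-identical so the filtered database
emitted at the end of the pipeline is a faithful subset of the input.
Organism names are recovered from the UniProt ``OS=`` header convention;
headers without it fall into an ``"unknown"`` bucket.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Output line-wrap width for sequence lines (common FASTA dialect; keeps
#: outputs bit-stable for comparison across runs).
WRAP_WIDTH = 60

_OS_RE = re.compile(r"OS=(.*?)(?:\s+[A-Z][A-Z0-9]=|$)")


def extract_organism(header: str) -> str:
    """Organism name from a FASTA description line (without leading '>').

    Returns the value of the ``OS=`` key up to the next `` XX=`` key token,
    or ``"unknown"`` when no such key is present.  Total function: never
    raises.
    """
    m = _OS_RE.search(header)
    if m:
        name = m.group(1).strip()
        if name:
            return name
    return "unknown"


@dataclass
class ProteinRecord:
    """One FASTA entry with its parsed organism."""

    accession: str
    header: str
    sequence: str
    organism: str = field(default="")

    def __post_init__(self) -> None:
        if not self.organism:
            self.organism = extract_organism(self.header)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(source: Union[str, Path, IO[str]]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _checked_lines(handle: IO[str]) -> Iterator[str]:
    """Yield lines, failing loudly if sequence data precedes the first header."""
    first_content_seen = False
    for lineno, line in enumerate(handle, start=1):
        if not first_content_seen and line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"FASTA parse error at line {lineno}: sequence data "
                    "before first '>' header"
                )
            first_content_seen = True
        yield line


def read_fasta(source: Union[str, Path, IO[str]]) -> List[ProteinRecord]:
    """Parse a FASTA stream or path into an ordered list of ProteinRecord.

    Sequences are concatenated across wrapped lines and upper-cased.  Records
    with empty sequences are skipped with a warning.  Duplicate accessions are
    both kept: the second and later copies get an ordinal suffix (``#2``, …)
    so downstream keying stays unique, and a warning is emitted.
    """
    handle = _open_text(source)
    close = handle is not source
    records: List[ProteinRecord] = []
    seen: dict[str, int] = {}
    try:
        for header, seq in SimpleFastaParser(_checked_lines(handle)):
            seq = seq.upper()
            if not seq:
                logger.warning("skipping FASTA record with empty sequence: %r", header)
                continue
            accession = header.split(None, 1)[0] if header else ""
            n = seen.get(accession, 0) + 1
            seen[accession] = n
            if n > 1:
                logger.warning(
                    "duplicate accession %r (occurrence %d); keyed as %r",
                    accession, n, f"{accession}#{n}",
                )
                accession = f"{accession}#{n}"
            records.append(ProteinRecord(accession=accession, header=header, sequence=seq))
    finally:
        if close:
            handle.close()
    return records


def write_fasta(
    records: Iterable[ProteinRecord],
    dest: Union[str, Path, IO[str]],
    width: int = WRAP_WIDTH,
) -> None:
    """Write records in order, headers byte-identical, sequences wrapped.

    LF line endings; an empty collection produces an empty file with a
    warning.
    """
    records = list(records)
    if not records:
        logger.warning("writing empty FASTA file (no records)")
    if hasattr(dest, "write"):
        handle, close = dest, False  # type: ignore[assignment]
    else:
        handle, close = open(dest, "wt", newline="\n"), True
    try:
        for rec in records:
            handle.write(f">{rec.header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
    finally:
        if close:
            handle.close()
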