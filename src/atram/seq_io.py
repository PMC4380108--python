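"""Sequence I/O: FASTA/FASTQ reading, read-pair normalization, FASTA writing.

All sequences are held uppercase; ``U`` is mapped to ``T`` on input so RNA-coded
archives behave like DNA. Phred qualities (Sanger/Illumina 1.8+, Phred+33) are
parsed when the source is FASTQ but the assembly method itself is
quality-agnostic, so they are dropped when a read database is built.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "ParseError",
    "PairingError",
    "read_sequences",
    "canonical_pair_id",
    "pair_records",
    "write_fasta",
]


class ParseError(ValueError):
    """A malformed FASTA/FASTQ record (named in the message)."""


class PairingError(ValueError):
    """Reads could not be grouped into mated pairs."""


_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its header, uppercase internally.

    ``id`` is the first whitespace-delimited token of the header and
    ``description`` the remainder (possibly empty). ``qualities`` is present
    iff the source was FASTQ.
    """

    id: str
    sequence: str
    description: str = ""
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"invalid record id {self.id!r}")
        if len(self.sequence) < 1:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """The two mated reads of one sequenced fragment."""

    pair_id: str
    read1: SequenceRecord
    read2: SequenceRecord


# Trailing mate-end markers: frag/1, frag.1, frag_1.
_SUFFIX_RE = re.compile(r"^(.*?)[/._]([12])$")


def canonical_pair_id(read_id: str) -> tuple[str, int | None]:
    """Strip a mate-end suffix from a read id.

    Returns ``(pair_id, end)`` where ``end`` is 1, 2 or ``None`` when the id
    carries no recognized suffix. Casava 1.8 style ids keep the end in the
    comment field (``"frag 1:N:0:AGTC"``); that form is handled by callers that
    still have the description, via :func:`casava_end`.
    """
    if not read_id:
        raise ValueError("empty read id")
    m = _SUFFIX_RE.match(read_id)
    if m:
        return m.group(1), int(m.group(2))
    return read_id, None


_CASAVA_RE = re.compile(r"^([12]):[YN]:\d+:\S*$")


def casava_end(description: str) -> int | None:
    """Mate end encoded in a Casava 1.8+ comment field, if any."""
    first = description.split()[0] if description else ""
    m = _CASAVA_RE.match(first)
    return int(m.group(1)) if m else None


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return "fasta"  # empty file: harmless either way
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot auto-detect format from first character {first!r}")


def read_sequences(
    path: str | Path, format: Literal["fasta", "fastq", "auto"] = "auto"
) -> list[SequenceRecord]:
    """Read all records from a FASTA/FASTQ file (gzip accepted by extension)."""
    fmt = _detect_format(path) if format == "auto" else format
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                seq = str(rec.seq).upper().translate(_U_TO_T).upper()
                quals = rec.letter_annotations.get("phred_quality")
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                try:
                    records.append(
                        SequenceRecord(
                            id=rec.id,
                            sequence=seq,
                            description=desc,
                            qualities=tuple(quals) if quals is not None else None,
                        )
                    )
                except ParseError as exc:
                    raise ParseError(f"{path}, record {i + 1}: {exc}") from exc
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            # Biopython signals malformed FASTQ (e.g. quality/sequence length
            # mismatch) with ValueError; re-raise naming the file.
            raise ParseError(f"{path}: {exc}") from exc
    return records


def pair_records(
    source: Literal["two_files", "interleaved", "suffixed_single_file"],
    records1: Sequence[SequenceRecord],
    records2: Sequence[SequenceRecord] | None = None,
    *,
    warn: callable = None,
) -> list[ReadPair]:
    """Group reads into mated :class:`ReadPair` objects.

    ``two_files``: positional pairing of two equal-length lists; id-suffix
    disagreement is advisory (reported through ``warn``) because many archives
    drop the suffixes. ``interleaved``: consecutive records of ``records1`` are
    mates. ``suffixed_single_file``: reads matched purely by canonical id and
    their /1 /2 suffixes.
    """
    pairs: list[ReadPair] = []
    if source == "two_files":
        if records2 is None:
            raise PairingError("two_files requires a second record list")
        if len(records1) != len(records2):
            raise PairingError(
                f"unequal file lengths: {len(records1)} vs {len(records2)} records"
            )
        for r1, r2 in zip(records1, records2):
            pid1, e1 = canonical_pair_id(r1.id)
            pid2, e2 = canonical_pair_id(r2.id)
            if e1 is not None and e2 is not None and pid1 != pid2:
                msg = f"mate id mismatch at {r1.id!r} / {r2.id!r}"
                if warn is not None:
                    warn(msg)
            pairs.append(ReadPair(pair_id=pid1, read1=r1, read2=r2))
    elif source == "interleaved":
        if records2 is not None:
            raise PairingError("interleaved takes a single record list")
        if len(records1) % 2 != 0:
            raise PairingError(f"odd record count {len(records1)} in interleaved input")
        for r1, r2 in zip(records1[0::2], records1[1::2]):
            pid1, e1 = canonical_pair_id(r1.id)
            pid2, e2 = canonical_pair_id(r2.id)
            if e1 is not None and e2 is not None and pid1 != pid2:
                raise PairingError(f"mate id mismatch at {r1.id!r} / {r2.id!r}")
            pairs.append(ReadPair(pair_id=pid1, read1=r1, read2=r2))
    elif source == "suffixed_single_file":
        if records2 is not None:
            raise PairingError("suffixed_single_file takes a single record list")
        by_pid: dict[str, dict[int, SequenceRecord]] = {}
        order: list[str] = []
        for r in records1:
            pid, end = canonical_pair_id(r.id)
            if end is None:
                end = casava_end(r.description)
            if end is None:
                raise PairingError(f"read {r.id!r} carries no recognizable mate suffix")
            slot = by_pid.setdefault(pid, {})
            if end in slot:
                raise PairingError(f"duplicate mate {end} for pair {pid!r}")
            if not slot:
                order.append(pid)
            slot[end] = r
        for pid in order:
            slot = by_pid[pid]
            if set(slot) != {1, 2}:
                raise PairingError(f"pair {pid!r} is missing mate {3 - next(iter(slot))}")
            pairs.append(ReadPair(pair_id=pid, read1=slot[1], read2=slot[2]))
    else:
        raise ValueError(f"unknown pairing source {source!r}")
    return pairs


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 70
) -> Path:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")
    return path


def write_fastq(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write pairs as two mate FASTQ files (uniform qualities if absent)."""

    def dump(fh, rec: SequenceRecord, end: int) -> None:
        quals = rec.qualities or (40,) * len(rec.sequence)
        qstr = "".join(chr(q + 33) for q in quals)
        fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")

    with open(path1, "wt") as f1, open(path2, "wt") as f2:
        for p in pairs:
            dump(f1, p.read1, 1)
            dump(f2, p.read2, 2)
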