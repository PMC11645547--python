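"""Byte-exact FASTA/FASTQ I/O and channel splitting.

A compressor must reproduce its input bit for bit, so records keep not just
header and sequence text but the original line layout (the lengths of the
wrapped sequence lines) and whether the file ended with a newline.  A record
stream is split into independent channels — headers, 2-bit sequence symbols,
an exception side-channel for non-ACGT characters, a case mask for
soft-masked (lowercase) runs, qualities, and layout metadata — and
``merge_streams`` is the exact inverse.

Only ``\\n`` line endings are supported; a ``\\r`` anywhere fails fast so the
reconstruction contract stays unambiguous.  FASTQ records must be the
standard four-line form (no wrapped sequence or quality lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "SymbolAlphabet",
    "SequenceRecord",
    "SplitStreams",
    "FormatError",
    "DNA",
    "read_records",
    "split_streams",
    "merge_streams",
    "sniff_format",
]


class FormatError(ValueError):
    """Malformed input file; the message names the byte offset where known."""


@dataclass(frozen=True)
class SymbolAlphabet:
    """The source alphabet Σ over which the models predict.

    The core DNA alphabet is ``ACGT`` (indices 0..3).  Any character outside
    it is replaced in the symbol channel by a placeholder index and recorded
    losslessly in the exception side-channel.
    """

    symbols: tuple[str, ...] = ("A", "C", "G", "T")

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index_of(self, ch: str) -> Optional[int]:
        try:
            return self.symbols.index(ch)
        except ValueError:
            return None


DNA = SymbolAlphabet()

_DNA_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = (3, 2, 1, 0)  # A<->T, C<->G as indices


@dataclass
class SequenceRecord:
    """One FASTA/FASTQ record with enough metadata for exact reconstruction.

    ``header`` excludes the leading ``>``/``@``.  ``line_layout`` lists the
    byte length of each original sequence line (a blank line is 0).
    ``plus_line`` keeps whatever followed the ``+`` separator in FASTQ.
    """

    header: str
    sequence: str
    qualities: Optional[str] = None
    line_layout: list[int] = field(default_factory=list)
    plus_line: str = ""

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.header!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class SplitStreams:
    """Per-channel view of a record stream.

    ``symbols`` concatenates all records' sequences as alphabet indices
    (case-folded, exceptions replaced by the placeholder).  ``exceptions``
    are (global position, original uppercase character).  ``case_runs`` is a
    run-length encoding of the lowercase mask over the concatenated
    sequence, starting with an uppercase run (possibly 0).
    """

    fmt: str  # "fasta" | "fastq" | "raw"
    headers: list[str]
    plus_lines: list[str]
    layouts: list[list[int]]
    symbols: list[int]
    exceptions: list[tuple[int, str]]
    case_runs: list[int]
    qualities: Optional[str]
    final_newline: bool

    @property
    def n_records(self) -> int:
        return len(self.headers)


def sniff_format(data: bytes) -> str:
    """Guess fasta/fastq from the first non-blank byte."""
    for b in data:
        if b in (0x0A,):
            continue
        if b == ord(">"):
            return "fasta"
        if b == ord("@"):
            return "fastq"
        raise FormatError(
            f"cannot sniff format: first non-blank byte {chr(b)!r} is neither '>' nor '@'"
        )
    return "fasta"  # empty file: treat as empty FASTA


def _check_no_cr(data: bytes) -> None:
    idx = data.find(b"\r")
    if idx >= 0:
        raise FormatError(
            f"carriage return at byte offset {idx}: only \\n line endings are supported"
        )


def _split_lines(data: bytes) -> tuple[list[str], bool]:
    """Split into lines; report whether the file ended with a newline."""
    text = data.decode("latin-1")
    if not text:
        return [], False
    final_newline = text.endswith("\n")
    lines = text.split("\n")
    if final_newline:
        lines.pop()
    return lines, final_newline


def read_records(
    data: bytes, fmt: str = "auto"
) -> tuple[list[SequenceRecord], str, bool]:
    """Parse FASTA/FASTQ bytes into records.

    Returns ``(records, fmt, final_newline)``.  ``fmt="auto"`` sniffs from
    the first non-blank byte.  Malformed input raises :class:`FormatError`
    naming the byte offset of the offending line.
    """
    _check_no_cr(data)
    if fmt == "auto":
        fmt = sniff_format(data)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    lines, final_newline = _split_lines(data)
    if fmt == "fasta":
        records = _parse_fasta(lines, data)
    else:
        records = _parse_fastq(lines, data)
    return records, fmt, final_newline


def _offset_of_line(data: bytes, line_no: int) -> int:
    off = 0
    for _ in range(line_no):
        off = data.find(b"\n", off) + 1
    return off


def _parse_fasta(lines: list[str], data: bytes) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    i = 0
    n = len(lines)
    # Leading blank lines before the first record are not representable in
    # the split-channel model; reject them (blank lines inside records are).
    while i < n:
        line = lines[i]
        if not line.startswith(">"):
            raise FormatError(
                f"expected '>' at byte offset {_offset_of_line(data, i)}, "
                f"got {line[:20]!r}"
            )
        header = line[1:]
        i += 1
        seq_parts: list[str] = []
        layout: list[int] = []
        while i < n and not lines[i].startswith(">"):
            seq_parts.append(lines[i])
            layout.append(len(lines[i]))
            i += 1
        records.append(
            SequenceRecord(header=header, sequence="".join(seq_parts), line_layout=layout)
        )
    return records


def _parse_fastq(lines: list[str], data: bytes) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    n = len(lines)
    if n % 4 != 0:
        raise FormatError(
            f"FASTQ line count {n} is not a multiple of 4 "
            f"(only four-line records are supported)"
        )
    for i in range(0, n, 4):
        head, seq, plus, qual = lines[i : i + 4]
        off = _offset_of_line(data, i)
        if not head.startswith("@"):
            raise FormatError(f"expected '@' at byte offset {off}, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(
                f"expected '+' separator at byte offset {_offset_of_line(data, i + 2)}"
            )
        if len(qual) != len(seq):
            raise FormatError(
                f"quality length {len(qual)} != sequence length {len(seq)} "
                f"for record at byte offset {off}"
            )
        records.append(
            SequenceRecord(
                header=head[1:],
                sequence=seq,
                qualities=qual,
                line_layout=[len(seq)],
                plus_line=plus[1:],
            )
        )
    return records


def split_streams(
    records: Iterable[SequenceRecord],
    fmt: str,
    alphabet: SymbolAlphabet = DNA,
    final_newline: bool = True,
) -> SplitStreams:
    """Split records into model-ready channels.

    Sequence characters are uppercased; lowercase positions go into the
    run-length case mask.  Characters outside the alphabet map to
    placeholder index 0 and are logged (position, uppercase char) in the
    exception channel.
    """
    headers: list[str] = []
    plus_lines: list[str] = []
    layouts: list[list[int]] = []
    symbols: list[int] = []
    exceptions: list[tuple[int, str]] = []
    case_runs: list[int] = [0]
    lower_run = False
    quals: list[str] = []
    has_quals = False
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    pos = 0
    for rec in records:
        headers.append(rec.header)
        plus_lines.append(rec.plus_line)
        layouts.append(list(rec.line_layout))
        if rec.qualities is not None:
            has_quals = True
            quals.append(rec.qualities)
        for ch in rec.sequence:
            is_lower = ch.islower()
            if is_lower != lower_run:
                case_runs.append(1)
                lower_run = is_lower
            else:
                case_runs[-1] += 1
            up = ch.upper()
            idx = index.get(up)
            if idx is None:
                symbols.append(0)
                exceptions.append((pos, up))
            else:
                symbols.append(idx)
            pos += 1
    return SplitStreams(
        fmt=fmt,
        headers=headers,
        plus_lines=plus_lines,
        layouts=layouts,
        symbols=symbols,
        exceptions=exceptions,
        case_runs=case_runs,
        qualities="".join(quals) if has_quals else None,
        final_newline=final_newline,
    )


def merge_streams(streams: SplitStreams, alphabet: SymbolAlphabet = DNA) -> bytes:
    """Reassemble the original file bytes from split channels.

    Exact inverse of ``read_records`` followed by ``split_streams``.
    """
    # Rebuild the concatenated sequence text.
    chars = [alphabet.symbols[s] for s in streams.symbols]
    for pos, ch in streams.exceptions:
        if pos >= len(chars):
            raise FormatError(f"exception position {pos} beyond sequence length")
        chars[pos] = ch
    pos = 0
    for i, run in enumerate(streams.case_runs):
        if i % 2 == 1:  # lowercase run
            for j in range(pos, pos + run):
                chars[j] = chars[j].lower()
        pos += run
    if streams.case_runs and pos != len(chars):
        raise FormatError(
            f"case-run total {pos} does not match sequence length {len(chars)}"
        )
    seq_text = "".join(chars)

    out: list[str] = []
    seq_off = 0
    qual_off = 0
    fq = streams.fmt == "fastq"
    raw = streams.fmt == "raw"
    n = streams.n_records
    if not (len(streams.plus_lines) == len(streams.layouts) == n):
        raise FormatError("inconsistent channel lengths across records")
    for r in range(n):
        layout = streams.layouts[r]
        length = sum(layout)
        if seq_off + length > len(seq_text):
            raise FormatError("layout exceeds sequence channel length")
        if not raw:
            out.append((("@" if fq else ">") + streams.headers[r]) + "\n")
        for ll in layout:
            out.append(seq_text[seq_off : seq_off + ll] + "\n")
            seq_off += ll
        if fq:
            if streams.qualities is None:
                raise FormatError("FASTQ streams lack a quality channel")
            out.append("+" + streams.plus_lines[r] + "\n")
            out.append(streams.qualities[qual_off : qual_off + length] + "\n")
            qual_off += length
    if seq_off != len(seq_text):
        raise FormatError(
            f"layout accounts for {seq_off} symbols but channel holds {len(seq_text)}"
        )
    text = "".join(out)
    if not streams.final_newline and text.endswith("\n"):
        text = text[:-1]
    return text.encode("latin-1")


def read_raw(data: bytes) -> tuple[list[SequenceRecord], str, bool]:
    """Read a headerless symbol file (``--raw`` mode) as one pseudo-record.

    Line structure is preserved through the layout channel like FASTA.
    """
    _check_no_cr(data)
    lines, final_newline = _split_lines(data)
    seq = "".join(lines)
    rec = SequenceRecord(header="", sequence=seq, line_layout=[len(l) for l in lines])
    return ([rec] if data else []), "raw", final_newline


def records_to_symbols(
    data: bytes, fmt: str = "auto", alphabet: SymbolAlphabet = DNA
) -> list[int]:
    """Convenience: file bytes straight to the symbol-index channel."""
    if fmt == "raw":
        records, fmt, fin = read_raw(data)
    else:
        records, fmt, fin = read_records(data, fmt)
    return split_streams(records, fmt, alphabet, fin).symbols
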