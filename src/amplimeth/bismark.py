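"""Streaming reader for Bismark methylation-extractor call files.

The extractor emits one line per sequenced cytosine::

    <read_id> TAB <state> TAB <chrom> TAB <1-based position> TAB <call letter>

where ``state`` is ``+`` (methylated) or ``-`` (unmethylated) and the call
letter encodes the sequence context: Z/z CpG, X/x CHG, H/h CHH, U/u unknown.
Uppercase means methylated; the letter case must agree with the state column.
An optional "Bismark methylation extractor" banner line is skipped.

Positions are converted to 0-based on input. CpG calls originating from the
original-bottom (OB) strand are reported at the G of the dinucleotide; they
can be shifted one base left onto the forward-strand C with
:func:`normalize_strand` so both bisulfite strands report the same site.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from .errors import ExtractorFormatError

log = logging.getLogger(__name__)

CONTEXT_BY_LETTER = {"Z": "CpG", "X": "CHG", "H": "CHH", "U": "unknown"}
LETTER_BY_CONTEXT = {v: k for k, v in CONTEXT_BY_LETTER.items()}

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class MethCall:
    """One cytosine observation on one read (0-based position)."""

    read_id: str
    chrom: str
    pos: int
    context: str  # CpG | CHG | CHH | unknown
    methylated: bool
    original_strand: str = FORWARD


@dataclass
class ParseStats:
    """Per-file tallies the parser accumulates while streaming."""

    data_lines: int = 0
    yielded: int = 0
    skipped_inconsistent: int = 0  # state symbol disagrees with letter case


def open_text_auto(path: Union[str, Path]) -> IO[str]:
    """Open plain or gzip text, sniffed from the two magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


_HEADER_RE = re.compile(r"Bismark methylation extractor", re.IGNORECASE)


def parse_extractor_file(
    stream: Iterable[str],
    stats: Optional[ParseStats] = None,
    source: str = "<stream>",
) -> Iterator[MethCall]:
    """Lazily yield one :class:`MethCall` per well-formed data line.

    Memory use is bounded by a single record. A wrong column count raises
    :class:`ExtractorFormatError` naming the line; a line whose ``+``/``-``
    state disagrees with the call letter's case is counted in
    ``stats.skipped_inconsistent`` and skipped.
    """
    if stats is None:
        stats = ParseStats()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if lineno == 1 and _HEADER_RE.search(line):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ExtractorFormatError(
                f"{source}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
            )
        stats.data_lines += 1
        read_id, state, chrom, pos_s, letter = fields
        if state not in "+-" or letter.upper() not in CONTEXT_BY_LETTER:
            raise ExtractorFormatError(
                f"{source}:{lineno}: unrecognized state {state!r} / call letter {letter!r}"
            )
        try:
            pos1 = int(pos_s)
        except ValueError as exc:
            raise ExtractorFormatError(
                f"{source}:{lineno}: non-integer position {pos_s!r}"
            ) from exc
        methylated = state == "+"
        if letter.isupper() != methylated:
            stats.skipped_inconsistent += 1
            log.debug("%s:%d: state %s disagrees with letter %s; record skipped",
                      source, lineno, state, letter)
            continue
        stats.yielded += 1
        yield MethCall(
            read_id=read_id,
            chrom=chrom,
            pos=pos1 - 1,
            context=CONTEXT_BY_LETTER[letter.upper()],
            methylated=methylated,
        )


def normalize_strand(call: MethCall, strand_of_read: str) -> MethCall:
    """Collapse a CpG call onto the forward-strand C position.

    A reverse-strand (OB) CpG call is reported at the G and is shifted one
    base left; forward-strand calls pass through. The originating strand is
    recorded on the returned call.
    """
    if call.context != "CpG":
        raise ValueError("normalize_strand applies to CpG calls only")
    if strand_of_read == REVERSE:
        return replace(call, pos=call.pos - 1, original_strand=REVERSE)
    return replace(call, original_strand=FORWARD)


_OB_TOKEN = re.compile(r"(?:^|[._])(?:CTOB|OB)(?:[._]|$)", re.IGNORECASE)
_OT_TOKEN = re.compile(r"(?:^|[._])(?:CTOT|OT)(?:[._]|$)", re.IGNORECASE)


def strand_from_filename(path: Union[str, Path]) -> Optional[str]:
    """Infer the bisulfite strand from extractor filename tokens.

    Bismark names its per-strand outputs with OT/OB (and CTOT/CTOB) tokens,
    e.g. ``CpG_OT_sample.txt``. Returns "forward" for OT, "reverse" for OB,
    or None when no token is present.
    """
    name = Path(path).name
    if _OB_TOKEN.search(name):
        return REVERSE
    if _OT_TOKEN.search(name):
        return FORWARD
    return None


def write_extractor_file(calls: Iterable[MethCall], handle: IO[str]) -> int:
    """Canonical writer for the extractor format (1-based positions).

    Inverse of :func:`parse_extractor_file`; used by the simulator and in
    round-trip tests. Returns the number of lines written.
    """
    n = 0
    for c in calls:
        letter = LETTER_BY_CONTEXT[c.context]
        if not c.methylated:
            letter = letter.lower()
        state = "+" if c.methylated else "-"
        handle.write(f"{c.read_id}\t{state}\t{c.chrom}\t{c.pos + 1}\t{letter}\n")
        n += 1
    return n
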