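"""Amplicon definitions and sample manifests.

A targeted bisulfite experiment is described by a BED-like tab-separated
config: one line per PCR amplicon giving its genomic interval and the lengths
of the two primers. Bases under the primer-annealing sequence carry the
primer's cytosines, not the template's methylation state, so CpG scoring is
restricted to the primer-trimmed interior of each amplicon.

Internally every interval is 0-based half-open (BED convention). Genome
browser style ``chr:start-end`` spans, which are 1-based fully closed, are
converted on input when ``coordinate_style="ucsc"`` is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, TextIO, Tuple, Union

from .errors import ConfigError

log = logging.getLogger(__name__)

#: accepted values for the ``coordinate_style`` argument
COORDINATE_STYLES = ("bed", "ucsc")


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR target region with primer-trimmed CpG territory.

    Coordinates are 0-based half-open regardless of the input style.
    """

    name: str
    chrom: str
    start: int
    end: int
    fwd_primer_len: int = 0
    rev_primer_len: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("amplicon name must be non-empty")
        if not self.chrom:
            raise ConfigError(f"amplicon {self.name!r}: chrom must be non-empty")
        if self.start < 0:
            raise ConfigError(f"amplicon {self.name!r}: start must be >= 0")
        if self.start >= self.end:
            raise ConfigError(
                f"amplicon {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise ConfigError(f"amplicon {self.name!r}: primer lengths must be >= 0")
        if self.fwd_primer_len + self.rev_primer_len >= self.end - self.start:
            raise ConfigError(
                f"amplicon {self.name!r}: primers ({self.fwd_primer_len}+"
                f"{self.rev_primer_len}) leave no interior in a "
                f"{self.end - self.start} bp amplicon"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: name, free-text description, optional accession."""

    sample_name: str
    description: str = ""
    accession: str = ""


def trimmed_interval(a: AmpliconDef) -> Tuple[int, int]:
    """Interval inside which CpG sites are scored: the amplicon minus primers.

    Returns the 0-based half-open ``[start + fwd_primer_len, end - rev_primer_len)``.
    Non-empty by construction (the :class:`AmpliconDef` invariant guarantees
    the primers do not cover the whole amplicon).
    """
    return a.start + a.fwd_primer_len, a.end - a.rev_primer_len


def _data_lines(handle: TextIO) -> Iterable[Tuple[int, str]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_amplicon_config(
    path: Union[str, Path, TextIO],
    coordinate_style: str = "bed",
) -> List[AmpliconDef]:
    """Parse a BED-like amplicon config into an ordered list of definitions.

    Columns (tab-separated): chrom, start, end, name, and optionally forward
    and reverse primer length. ``#``-prefixed lines are comments. With
    ``coordinate_style="ucsc"`` the start/end columns are taken as 1-based
    fully closed and converted to the internal 0-based half-open convention.

    Raises :class:`ConfigError` for malformed lines (naming the line number),
    invalid intervals, or duplicate amplicon names.
    """
    if coordinate_style not in COORDINATE_STYLES:
        raise ConfigError(
            f"coordinate_style must be one of {COORDINATE_STYLES}, got {coordinate_style!r}"
        )
    if hasattr(path, "read"):
        return _parse_amplicon_stream(path, coordinate_style, "<stream>")
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_amplicon_stream(fh, coordinate_style, str(path))


def _parse_amplicon_stream(
    handle: TextIO, coordinate_style: str, source: str
) -> List[AmpliconDef]:
    out: List[AmpliconDef] = []
    seen: set[str] = set()
    warned_primerless = False
    for lineno, line in _data_lines(handle):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ConfigError(
                f"{source}:{lineno}: expected >= 4 tab-separated columns "
                f"(chrom, start, end, name), got {len(fields)}"
            )
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ConfigError(f"{source}:{lineno}: non-integer coordinate: {exc}") from exc
        if coordinate_style == "ucsc":
            start -= 1  # 1-based closed -> 0-based half-open
        if len(fields) >= 6:
            try:
                fwd, rev = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ConfigError(
                    f"{source}:{lineno}: non-integer primer length: {exc}"
                ) from exc
        else:
            fwd = rev = 0
            if not warned_primerless:
                log.warning(
                    "%s: primer-length columns absent; defaulting to 0 "
                    "(CpG sites under primers will be scored)",
                    source,
                )
                warned_primerless = True
        if name in seen:
            raise ConfigError(f"{source}:{lineno}: duplicate amplicon name {name!r}")
        seen.add(name)
        try:
            out.append(AmpliconDef(name, chrom, start, end, fwd, rev))
        except ConfigError as exc:
            raise ConfigError(f"{source}:{lineno}: {exc}") from exc
    return out


def write_amplicon_config(amplicons: Iterable[AmpliconDef], path: Union[str, Path]) -> None:
    """Serialize definitions back to the 6-column BED-like format (0-based)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# amplimeth amplicon config (0-based half-open coordinates)\n")
        fh.write("# chrom\tstart\tend\tname\tfwd_primer_len\trev_primer_len\n")
        for a in amplicons:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\t"
                f"{a.fwd_primer_len}\t{a.rev_primer_len}\n"
            )


def parse_sample_manifest(path: Union[str, Path, TextIO]) -> List[SampleRecord]:
    """Parse a tab-separated sample manifest.

    Requires a header line ``sample_name<TAB>description[<TAB>accession]``;
    ``#`` comment lines are ignored. Duplicate sample names are rejected.
    """
    if hasattr(path, "read"):
        return _parse_manifest_stream(path, "<stream>")
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_manifest_stream(fh, str(path))


def _parse_manifest_stream(handle: TextIO, source: str) -> List[SampleRecord]:
    records: List[SampleRecord] = []
    seen: set[str] = set()
    header_seen = False
    for lineno, line in _data_lines(handle):
        fields = line.split("\t")
        if not header_seen:
            if fields[0].strip().lower() != "sample_name":
                raise ConfigError(
                    f"{source}:{lineno}: manifest must start with a "
                    "'sample_name...' header line"
                )
            header_seen = True
            continue
        name = fields[0]
        if not name:
            raise ConfigError(f"{source}:{lineno}: empty sample_name")
        if name in seen:
            raise ConfigError(f"{source}:{lineno}: duplicate sample_name {name!r}")
        seen.add(name)
        desc = fields[1] if len(fields) > 1 else ""
        acc = fields[2] if len(fields) > 2 else ""
        records.append(SampleRecord(name, desc, acc))
    if not header_seen:
        raise ConfigError(f"{source}: manifest has no header line")
    return records
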