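"""Per-read methylation patterns (epialleles) and their counts.

Each sequencing read reports the methylation state of every CpG site it
covers. Writing those states in genomic order gives the read's epiallele:
a string over '1' (methylated), '0' (unmethylated) and '-' (site not covered
by this read). Counting distinct strings per amplicon preserves the allelic
structure that a per-site average methylation fraction destroys: 50% average
methylation may be a homogeneous half-methylated population or a 50/50 mix of
fully methylated and fully unmethylated molecules, and only the pattern
counts distinguish the two.

The CpG site set of an amplicon is discovered empirically as the union of
observed CpG call positions inside the primer-trimmed interval; no reference
genome is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .amplicons import AmpliconDef, trimmed_interval
from .bismark import MethCall

MISSING = "-"


@dataclass(frozen=True)
class SiteIndex:
    """The ordered CpG positions observed within one amplicon's trimmed span."""

    amplicon: AmpliconDef
    sites: Tuple[int, ...]

    def __post_init__(self):
        lo, hi = trimmed_interval(self.amplicon)
        if any(not (lo <= s < hi) for s in self.sites):
            raise ValueError(f"site outside trimmed interval [{lo},{hi}) of "
                             f"{self.amplicon.name}")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing")


@dataclass(frozen=True)
class ReadPattern:
    """One read's ordered methylation states over an amplicon's CpG sites."""

    read_id: str
    amplicon_name: str
    pattern: str

    @property
    def coverage_fraction(self) -> float:
        """Fraction of the amplicon's sites this read actually covers."""
        if not self.pattern:
            return 0.0
        return 1.0 - self.pattern.count(MISSING) / len(self.pattern)


@dataclass(frozen=True)
class PatternRow:
    pattern: str
    count: int
    fraction: float


@dataclass(frozen=True)
class PatternSummary:
    """Counted, ranked epialleles for one amplicon in one sample.

    ``rows`` are sorted by count descending, ties broken lexicographically by
    pattern string. ``site_meth_fraction[i]`` is the fraction of methylated
    calls among kept reads covering site i (None when no kept read covers it).
    """

    amplicon: AmpliconDef
    sample_name: str
    sites: Tuple[int, ...]
    rows: Tuple[PatternRow, ...]
    total_reads: int
    dropped_reads: int
    site_meth_fraction: Tuple[Optional[float], ...]

    @property
    def amplicon_name(self) -> str:
        return self.amplicon.name


@dataclass
class QCReport:
    """Bisulfite-conversion and parsing diagnostics for one sample.

    ``conversion_rate`` is the fraction of non-CpG cytosine calls (CHG+CHH)
    read as unmethylated. Mammalian methylation is almost exclusively CpG, so
    a methylated non-CpG call nearly always means a cytosine that escaped
    bisulfite conversion; rates near 1.0 indicate successful treatment.
    None (flagged undefined) when no non-CpG calls were seen.
    """

    sample_name: str
    conversion_rate: Optional[float] = None
    context_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    malformed_records: int = 0
    call_conflicts: int = 0

    @property
    def conversion_defined(self) -> bool:
        return self.conversion_rate is not None


def build_site_index(calls: Iterable[MethCall], amplicon: AmpliconDef) -> SiteIndex:
    """Collect the sorted unique CpG positions inside the trimmed interval.

    Calls on other chromosomes, outside the trimmed span, or in non-CpG
    context are ignored. An empty site set is legal — it is exactly what the
    no-CpG control amplicon produces.
    """
    lo, hi = trimmed_interval(amplicon)
    sites = {
        c.pos
        for c in calls
        if c.context == "CpG" and c.chrom == amplicon.chrom and lo <= c.pos < hi
    }
    return SiteIndex(amplicon=amplicon, sites=tuple(sorted(sites)))


def assemble_patterns(
    calls: Iterable[MethCall],
    index: SiteIndex,
    conflict_counter: Optional[QCReport] = None,
) -> List[ReadPattern]:
    """Build one :class:`ReadPattern` per read with >= 1 call on index sites.

    Duplicate calls for the same (read, site) — e.g. overlapping mate pairs —
    are resolved first-seen-wins; disagreeing duplicates are tallied on
    ``conflict_counter.call_conflicts`` when a report is given. Output order
    is first appearance of each read, which makes downstream files
    reproducible for a given input order (counting itself is order-invariant).
    """
    site_pos = {pos: i for i, pos in enumerate(index.sites)}
    states: Dict[str, Dict[int, bool]] = {}
    order: List[str] = []
    for c in calls:
        if c.context != "CpG" or c.chrom != index.amplicon.chrom:
            continue
        i = site_pos.get(c.pos)
        if i is None:
            continue
        per_read = states.get(c.read_id)
        if per_read is None:
            states[c.read_id] = {i: c.methylated}
            order.append(c.read_id)
        elif i in per_read:
            if per_read[i] != c.methylated and conflict_counter is not None:
                conflict_counter.call_conflicts += 1
        else:
            per_read[i] = c.methylated
    n = len(index.sites)
    out = []
    for read_id in order:
        chars = [MISSING] * n
        for i, meth in states[read_id].items():
            chars[i] = "1" if meth else "0"
        out.append(ReadPattern(read_id, index.amplicon.name, "".join(chars)))
    return out


def count_patterns(
    patterns: Iterable[ReadPattern],
    index: SiteIndex,
    sample_name: str = "sample",
    min_coverage_fraction: float = 1.0,
) -> PatternSummary:
    """Aggregate identical pattern strings into ranked epiallele counts.

    Reads covering fewer than ``min_coverage_fraction`` of the amplicon's
    sites are dropped (and counted); the remainder are grouped by exact
    string, ranked by count descending with lexicographic tie-break, and the
    per-site methylation fraction is computed over covering kept reads only.
    Empty input yields an empty summary, not an error.
    """
    if not 0.0 <= min_coverage_fraction <= 1.0:
        raise ValueError("min_coverage_fraction must be in [0, 1]")
    counts: Dict[str, int] = {}
    dropped = 0
    for p in patterns:
        if p.coverage_fraction < min_coverage_fraction:
            dropped += 1
            continue
        counts[p.pattern] = counts.get(p.pattern, 0) + 1
    total = sum(counts.values())
    rows = tuple(
        PatternRow(pat, cnt, cnt / total)
        for pat, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    smf: List[Optional[float]] = []
    for i in range(len(index.sites)):
        meth = cov = 0
        for pat, cnt in counts.items():
            if pat[i] != MISSING:
                cov += cnt
                if pat[i] == "1":
                    meth += cnt
        smf.append(meth / cov if cov else None)
    return PatternSummary(
        amplicon=index.amplicon,
        sample_name=sample_name,
        sites=index.sites,
        rows=rows,
        total_reads=total,
        dropped_reads=dropped,
        site_meth_fraction=tuple(smf),
    )


def compute_qc(calls: Iterable[MethCall], sample_name: str = "sample") -> QCReport:
    """Tally non-CpG methylation into a bisulfite-conversion estimate.

    conversion_rate = unmethylated non-CpG calls / all non-CpG calls, over
    CHG + CHH contexts. Unknown-context calls are ignored. With zero non-CpG
    calls the rate is undefined (None) and flagged via ``conversion_defined``.
    """
    ctx = {k: {"methylated": 0, "unmethylated": 0} for k in ("CpG", "CHG", "CHH")}
    for c in calls:
        if c.context in ctx:
            ctx[c.context]["methylated" if c.methylated else "unmethylated"] += 1
    non_cpg = ctx["CHG"]["methylated"] + ctx["CHG"]["unmethylated"] \
        + ctx["CHH"]["methylated"] + ctx["CHH"]["unmethylated"]
    rate = None
    if non_cpg:
        rate = (ctx["CHG"]["unmethylated"] + ctx["CHH"]["unmethylated"]) / non_cpg
    return QCReport(sample_name=sample_name, conversion_rate=rate, context_counts=ctx)
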