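"""Shared fixtures and the independent brute-force pattern-counting oracle."""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Tuple

import pytest
from hypothesis import HealthCheck, settings

from amplimeth import AmpliconDef, MethCall, ReadPattern, SiteIndex

settings.register_profile(
    "fixed",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("fixed")


# ---------------------------------------------------------------------------
# brute-force oracle: naive re-count of epiallele strings, written without
# reference to the implementation (plain loops, list.count, explicit sort)

def brute_force_count(
    pattern_strings: List[str], min_coverage_fraction: float
) -> Tuple[List[Tuple[str, int]], int, List[Optional[float]]]:
    """Return (ranked rows, dropped count, per-site methylation fractions)."""
    kept: List[str] = []
    dropped = 0
    for p in pattern_strings:
        coverage = 1.0 - p.count("-") / len(p) if p else 0.0
        if coverage >= min_coverage_fraction:
            kept.append(p)
        else:
            dropped += 1
    distinct = sorted(set(kept))
    rows = [(p, kept.count(p)) for p in distinct]
    rows.sort(key=lambda row: (-row[1], row[0]))
    n_sites = len(pattern_strings[0]) if pattern_strings else 0
    fractions: List[Optional[float]] = []
    for i in range(n_sites):
        covering = [p for p in kept if p[i] != "-"]
        if covering:
            fractions.append(sum(1 for p in covering if p[i] == "1") / len(covering))
        else:
            fractions.append(None)
    return rows, dropped, fractions


# ---------------------------------------------------------------------------
# small builders

def make_amplicon(name="amp", chrom="chr1", start=100, end=200, fwd=0, rev=0):
    return AmpliconDef(name, chrom, start, end, fwd, rev)


def make_read_patterns(strings: List[str], amplicon_name="amp") -> List[ReadPattern]:
    return [
        ReadPattern(f"read{i}", amplicon_name, s) for i, s in enumerate(strings)
    ]


def calls_for_patterns(
    strings: List[str], sites: List[int], chrom="chr1"
) -> List[MethCall]:
    """Expand pattern strings into the per-cytosine calls that encode them."""
    calls = []
    for i, s in enumerate(strings):
        for j, ch in enumerate(s):
            if ch == "-":
                continue
            calls.append(MethCall(f"read{i}", chrom, sites[j], "CpG", ch == "1"))
    return calls


def random_pattern_fixture(rng: random.Random) -> Tuple[List[str], float]:
    """A random epiallele fixture: <= 50 reads over <= 8 sites."""
    n_sites = rng.randint(1, 8)
    n_reads = rng.randint(1, 50)
    strings = []
    for _ in range(n_reads):
        while True:
            s = "".join(rng.choice("01-") for _ in range(n_sites))
            if s.count("-") < n_sites:
                break
        strings.append(s)
    threshold = rng.choice([0.0, rng.random(), 1.0])
    return strings, threshold


@pytest.fixture
def amplicon():
    return make_amplicon()


@pytest.fixture
def site_index(amplicon):
    return SiteIndex(amplicon=amplicon, sites=(110, 130, 150))
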