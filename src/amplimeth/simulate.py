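"""Synthetic Bismark-extractor data with known epiallele ground truth.

The generator emulates what a targeted bisulfite experiment hands to the
pattern counter: per-read CpG calls drawn from a declared epiallele mixture
for each amplicon, thinned by per-site dropout (sites a read fails to
report), plus a stream of non-CpG (CHH/CHG) calls whose methylation rate is
the bisulfite conversion error. It does not model raw reads, sequencing
error, or alignment artifacts — calls are emitted exactly as an error-free
extractor would.

Randomness comes from a single seeded NumPy PCG64 generator, so identical
specs produce byte-identical files; the RNG is named in the output metadata.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .amplicons import AmpliconDef, trimmed_interval
from .errors import SimSpecError

RNG_NAME = "numpy-PCG64"
FREQ_TOL = 1e-9


@dataclass(frozen=True)
class AmpliconSim:
    """Simulation settings for one amplicon.

    ``sites`` are the declared CpG positions (0-based, inside the trimmed
    interval); every key of ``epiallele_freqs`` is a full '0'/'1' string of
    that length. An amplicon with no sites (the no-CpG control) takes no
    epialleles and no reads — it only receives non-CpG calls.
    """

    amplicon: AmpliconDef
    sites: Tuple[int, ...]
    epiallele_freqs: Dict[str, float] = field(default_factory=dict)
    n_reads: int = 0


@dataclass(frozen=True)
class SimSpec:
    """Full study design for one simulated sample."""

    amplicons: Tuple[AmpliconSim, ...]
    dropout_rate: float = 0.0
    conversion_error: float = 0.0
    n_noncpg: int = 0
    seed: int = 0


def validate_spec(spec: SimSpec) -> None:
    """Raise :class:`SimSpecError` naming the first offending field."""
    if not spec.amplicons:
        raise SimSpecError("amplicons", "at least one amplicon required")
    for rate_name in ("dropout_rate", "conversion_error"):
        rate = getattr(spec, rate_name)
        if not (isinstance(rate, (int, float)) and 0.0 <= rate <= 1.0):
            raise SimSpecError(rate_name, f"must be in [0, 1], got {rate!r}")
    if spec.n_noncpg < 0:
        raise SimSpecError("n_noncpg", "must be >= 0")
    names = set()
    for sim in spec.amplicons:
        a = sim.amplicon
        ctx = f"amplicons[{a.name}]"
        if a.name in names:
            raise SimSpecError("amplicons", f"duplicate amplicon name {a.name!r}")
        names.add(a.name)
        lo, hi = trimmed_interval(a)
        if list(sim.sites) != sorted(set(sim.sites)):
            raise SimSpecError(f"{ctx}.sites", "must be strictly increasing")
        for s in sim.sites:
            if not lo <= s < hi:
                raise SimSpecError(
                    f"{ctx}.sites", f"site {s} outside trimmed interval [{lo},{hi})"
                )
        if sim.n_reads < 0:
            raise SimSpecError(f"{ctx}.n_reads", "must be >= 0")
        if not sim.sites:
            if sim.epiallele_freqs or sim.n_reads:
                raise SimSpecError(
                    f"{ctx}.epiallele_freqs",
                    "an amplicon without CpG sites takes no epialleles or reads",
                )
            continue
        if sim.n_reads > 0 and not sim.epiallele_freqs:
            raise SimSpecError(f"{ctx}.epiallele_freqs", "required when n_reads > 0")
        for pat, freq in sim.epiallele_freqs.items():
            if len(pat) != len(sim.sites) or any(ch not in "01" for ch in pat):
                raise SimSpecError(
                    f"{ctx}.epiallele_freqs",
                    f"pattern {pat!r} is not a 0/1 string of length {len(sim.sites)}",
                )
            if not 0.0 <= freq <= 1.0:
                raise SimSpecError(
                    f"{ctx}.epiallele_freqs", f"frequency {freq!r} outside [0, 1]"
                )
        if sim.epiallele_freqs and not math.isclose(
            sum(sim.epiallele_freqs.values()), 1.0, abs_tol=FREQ_TOL
        ):
            raise SimSpecError(
                f"{ctx}.epiallele_freqs",
                f"frequencies sum to {sum(sim.epiallele_freqs.values())!r}, not 1",
            )


def load_spec(path: Union[str, Path]) -> SimSpec:
    """Load and validate a JSON simulation spec.

    Layout::

        {"seed": 1, "dropout_rate": 0.0, "conversion_error": 0.01,
         "n_noncpg": 1000,
         "amplicons": [{"name": ..., "chrom": ..., "start": ..., "end": ...,
                        "fwd_primer_len": ..., "rev_primer_len": ...,
                        "sites": [...], "epiallele_freqs": {"101": 0.5, ...},
                        "n_reads": 1000}, ...]}
    """
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SimSpecError("<file>", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SimSpecError("<file>", "top level must be a JSON object")
    sims: List[AmpliconSim] = []
    for i, entry in enumerate(raw.get("amplicons", [])):
        ctx = f"amplicons[{i}]"
        for req in ("name", "chrom", "start", "end"):
            if req not in entry:
                raise SimSpecError(f"{ctx}.{req}", "missing")
        try:
            amp = AmpliconDef(
                name=entry["name"], chrom=entry["chrom"],
                start=int(entry["start"]), end=int(entry["end"]),
                fwd_primer_len=int(entry.get("fwd_primer_len", 0)),
                rev_primer_len=int(entry.get("rev_primer_len", 0)),
            )
        except Exception as exc:
            raise SimSpecError(ctx, str(exc)) from exc
        sims.append(AmpliconSim(
            amplicon=amp,
            sites=tuple(int(s) for s in entry.get("sites", [])),
            epiallele_freqs=dict(entry.get("epiallele_freqs", {})),
            n_reads=int(entry.get("n_reads", 0)),
        ))
    spec = SimSpec(
        amplicons=tuple(sims),
        dropout_rate=float(raw.get("dropout_rate", 0.0)),
        conversion_error=float(raw.get("conversion_error", 0.0)),
        n_noncpg=int(raw.get("n_noncpg", 0)),
        seed=int(raw.get("seed", 0)),
    )
    validate_spec(spec)
    return spec


#: truth table type: amplicon name -> pattern -> drawn count
TruthTable = Dict[str, Dict[str, int]]


def simulate_extractor_file(
    spec: SimSpec,
    out_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
) -> TruthTable:
    """Write a synthetic extractor file and return the drawn truth counts.

    For each amplicon, ``n_reads`` epialleles are drawn from the declared
    mixture; each CpG of each read is then dropped with ``dropout_rate`` and
    the survivors emitted as 1-based Z/z lines. ``n_noncpg`` CHH/CHG lines
    are spread round-robin over the amplicons at non-CpG positions, each
    methylated with probability ``conversion_error``. A fixed seed gives
    byte-identical output. The truth table (and its TSV, when ``truth_path``
    is given) records the drawn count of every epiallele before dropout.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    truth: TruthTable = {}
    opener = gzip.open if str(out_path).endswith(".gz") else open
    with opener(out_path, "wt", encoding="utf-8") as fh:
        fh.write(f"Bismark methylation extractor\tamplimeth-simulated\t"
                 f"version={__version__}\trng={RNG_NAME}\tseed={spec.seed}\n")
        for sim in spec.amplicons:
            truth[sim.amplicon.name] = _emit_amplicon_reads(sim, spec, rng, fh)
        _emit_noncpg_calls(spec, rng, fh)
    if truth_path is not None:
        _write_truth_tsv(truth, spec, truth_path)
    return truth


def _emit_amplicon_reads(sim, spec, rng, fh) -> Dict[str, int]:
    a = sim.amplicon
    if not sim.sites or sim.n_reads == 0:
        return {}
    patterns = sorted(sim.epiallele_freqs)  # fixed order for reproducibility
    probs = np.asarray([sim.epiallele_freqs[p] for p in patterns], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(patterns), size=sim.n_reads, p=probs)
    counts: Dict[str, int] = {}
    for i, k in enumerate(draws):
        pat = patterns[k]
        counts[pat] = counts.get(pat, 0) + 1
        read_id = f"{a.name}:read{i:06d}"
        if spec.dropout_rate > 0:
            keep = rng.random(len(sim.sites)) >= spec.dropout_rate
        else:
            keep = np.ones(len(sim.sites), dtype=bool)
        for j, site in enumerate(sim.sites):
            if not keep[j]:
                continue
            meth = pat[j] == "1"
            fh.write(f"{read_id}\t{'+' if meth else '-'}\t{a.chrom}\t"
                     f"{site + 1}\t{'Z' if meth else 'z'}\n")
    return counts


def _emit_noncpg_calls(spec, rng, fh) -> None:
    if spec.n_noncpg == 0:
        return
    # candidate non-CpG cytosine positions: trimmed-interval bases off the CpG sites
    pools: List[Tuple[AmpliconDef, np.ndarray]] = []
    for sim in spec.amplicons:
        lo, hi = trimmed_interval(sim.amplicon)
        mask = np.ones(hi - lo, dtype=bool)
        for s in sim.sites:
            mask[s - lo] = False
        positions = np.arange(lo, hi)[mask]
        if positions.size:
            pools.append((sim.amplicon, positions))
    if not pools:
        raise SimSpecError("n_noncpg", "no non-CpG positions available in any amplicon")
    for i in range(spec.n_noncpg):
        amp, positions = pools[i % len(pools)]
        pos = int(positions[int(rng.integers(positions.size))])
        context_letter = "H" if rng.random() < 0.8 else "X"  # mostly CHH, some CHG
        meth = bool(rng.random() < spec.conversion_error)
        letter = context_letter if meth else context_letter.lower()
        fh.write(f"{amp.name}:nonCpG{i:06d}\t{'+' if meth else '-'}\t"
                 f"{amp.chrom}\t{pos + 1}\t{letter}\n")


def _write_truth_tsv(truth: TruthTable, spec: SimSpec, path) -> None:
    lines = [f"# amplimeth simulation truth table\tversion={__version__}"
             f"\trng={RNG_NAME}\tseed={spec.seed}",
             f"# dropout_rate={spec.dropout_rate}"
             f"\tconversion_error={spec.conversion_error}"
             f"\tn_noncpg={spec.n_noncpg}",
             "amplicon\tpattern\ttrue_count"]
    for amp_name, counts in truth.items():
        for pat in sorted(counts):
            lines.append(f"{amp_name}\t{pat}\t{counts[pat]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_truth_tsv(path: Union[str, Path]) -> TruthTable:
    """Read a truth table back into ``{amplicon: {pattern: count}}``."""
    truth: TruthTable = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#") or not line or line.startswith("amplicon\t"):
            continue
        amp, pat, cnt = line.split("\t")
        truth.setdefault(amp, {})[pat] = int(cnt)
    return truth
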