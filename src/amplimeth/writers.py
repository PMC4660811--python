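"""Output writers: the tab-delimited pattern summary and the HTML report.

Two files summarize a sample. The TSV is the machine-readable product: one
row per (amplicon, epiallele) with its read count and within-amplicon
fraction, preceded by ``#`` metadata lines carrying tool version, run
parameters and per-amplicon totals so the file round-trips losslessly.

The HTML report is a single self-contained document — inline styling, no
external scripts or network fetches — showing, per amplicon, a grid of
patterns (columns = CpG sites in genomic order, rows = epialleles in rank
order) with read counts and percentages, a per-site methylation-fraction
track, and a bisulfite-conversion QC panel. The full summary data is embedded
as a JSON data island so the numbers can be re-extracted from the report.
"""

from __future__ import annotations

import json
from html import escape
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from . import __version__
from .amplicons import AmpliconDef
from .errors import AmplimethError
from .patterns import PatternRow, PatternSummary, QCReport

TSV_FORMAT_VERSION = 1
DATA_ISLAND_ID = "amplimeth-data"

TSV_COLUMNS = (
    "sample", "amplicon", "chrom", "start", "end",
    "n_sites", "site_positions", "pattern", "raw_count", "fraction",
)


# ---------------------------------------------------------------------------
# pattern summary TSV

def write_pattern_tsv(
    summaries: Iterable[PatternSummary],
    path: Union[str, Path],
    parameters: Optional[Mapping[str, object]] = None,
) -> None:
    """Write the per-sample pattern-count table.

    Rows are grouped by amplicon in the given (config) order and by pattern
    rank within each amplicon; coordinates are written 0-based half-open.
    Byte-identical across repeated runs on identical input.
    """
    summaries = list(summaries)
    sample = summaries[0].sample_name if summaries else ""
    lines: List[str] = []
    lines.append(f"# amplimeth pattern summary\tformat={TSV_FORMAT_VERSION}"
                 f"\tversion={__version__}")
    lines.append(f"# sample\t{sample}")
    for key, value in (parameters or {}).items():
        lines.append(f"# param\t{key}={value}")
    for s in summaries:
        a = s.amplicon
        lines.append(
            "# amplicon"
            f"\tname={a.name}\tchrom={a.chrom}\tstart={a.start}\tend={a.end}"
            f"\tfwd_primer_len={a.fwd_primer_len}\trev_primer_len={a.rev_primer_len}"
            f"\tsites={';'.join(str(p) for p in s.sites)}"
            f"\ttotal_reads={s.total_reads}\tdropped_reads={s.dropped_reads}"
        )
    lines.append("\t".join(TSV_COLUMNS))
    for s in summaries:
        a = s.amplicon
        site_str = ";".join(str(p) for p in s.sites)
        for row in s.rows:
            lines.append("\t".join((
                s.sample_name, a.name, a.chrom, str(a.start), str(a.end),
                str(len(s.sites)), site_str, row.pattern,
                str(row.count), f"{row.fraction:.6f}",
            )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pattern_tsv(path: Union[str, Path]) -> List[PatternSummary]:
    """Re-read a pattern TSV into the exact :class:`PatternSummary` list.

    Counts, ordering and site lists come straight from the file; fractions
    and per-site methylation levels are recomputed from the integer counts,
    reproducing the originals bit-for-bit.
    """
    meta: List[Dict[str, str]] = []
    rows_by_amp: Dict[str, List[Tuple[str, int]]] = {}
    sample = ""
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("# amplicon\t"):
                kv = dict(f.split("=", 1) for f in line.split("\t")[1:])
                meta.append(kv)
            elif line.startswith("# sample\t"):
                sample = line.split("\t", 1)[1]
            elif line.startswith("#") or not line:
                continue
            elif line.split("\t")[0] == "sample":
                continue  # header
            else:
                f = line.split("\t")
                if len(f) != len(TSV_COLUMNS):
                    raise AmplimethError(f"{path}: malformed data row: {line!r}")
                rows_by_amp.setdefault(f[1], []).append((f[7], int(f[8])))
    out: List[PatternSummary] = []
    for kv in meta:
        amp = AmpliconDef(
            name=kv["name"], chrom=kv["chrom"],
            start=int(kv["start"]), end=int(kv["end"]),
            fwd_primer_len=int(kv["fwd_primer_len"]),
            rev_primer_len=int(kv["rev_primer_len"]),
        )
        sites = tuple(int(p) for p in kv["sites"].split(";") if p != "")
        pat_counts = rows_by_amp.get(kv["name"], [])
        total = int(kv["total_reads"])
        rows = tuple(PatternRow(p, c, c / total) for p, c in pat_counts)
        smf: List[Optional[float]] = []
        for i in range(len(sites)):
            meth = cov = 0
            for p, c in pat_counts:
                if p[i] != "-":
                    cov += c
                    if p[i] == "1":
                        meth += c
            smf.append(meth / cov if cov else None)
        out.append(PatternSummary(
            amplicon=amp, sample_name=sample, sites=sites, rows=rows,
            total_reads=total, dropped_reads=int(kv["dropped_reads"]),
            site_meth_fraction=tuple(smf),
        ))
    return out


def write_qc_tsv(qc: QCReport, path: Union[str, Path]) -> None:
    """Write the conversion-QC report as key/value TSV."""
    lines = [f"# amplimeth QC report\tversion={__version__}",
             f"sample\t{qc.sample_name}",
             "conversion_rate\t" + (f"{qc.conversion_rate:.6f}"
                                    if qc.conversion_defined else "undefined")]
    for ctx in ("CpG", "CHG", "CHH"):
        counts = qc.context_counts.get(ctx, {})
        lines.append(f"{ctx}_methylated\t{counts.get('methylated', 0)}")
        lines.append(f"{ctx}_unmethylated\t{counts.get('unmethylated', 0)}")
    lines.append(f"malformed_records\t{qc.malformed_records}")
    lines.append(f"call_conflicts\t{qc.call_conflicts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON (de)serialization used by the HTML data island

def summary_to_dict(s: PatternSummary) -> dict:
    a = s.amplicon
    return {
        "amplicon": {"name": a.name, "chrom": a.chrom, "start": a.start,
                     "end": a.end, "fwd_primer_len": a.fwd_primer_len,
                     "rev_primer_len": a.rev_primer_len},
        "sample_name": s.sample_name,
        "sites": list(s.sites),
        "rows": [[r.pattern, r.count, r.fraction] for r in s.rows],
        "total_reads": s.total_reads,
        "dropped_reads": s.dropped_reads,
        "site_meth_fraction": list(s.site_meth_fraction),
    }


def summary_from_dict(d: Mapping) -> PatternSummary:
    return PatternSummary(
        amplicon=AmpliconDef(**d["amplicon"]),
        sample_name=d["sample_name"],
        sites=tuple(d["sites"]),
        rows=tuple(PatternRow(p, c, f) for p, c, f in d["rows"]),
        total_reads=d["total_reads"],
        dropped_reads=d["dropped_reads"],
        site_meth_fraction=tuple(d["site_meth_fraction"]),
    )


def qc_to_dict(qc: QCReport) -> dict:
    return {"sample_name": qc.sample_name,
            "conversion_rate": qc.conversion_rate,
            "context_counts": qc.context_counts,
            "malformed_records": qc.malformed_records,
            "call_conflicts": qc.call_conflicts}


def qc_from_dict(d: Mapping) -> QCReport:
    return QCReport(**d)


# ---------------------------------------------------------------------------
# HTML report

_CSS = """
body { font-family: -apple-system, 'Helvetica Neue', Arial, sans-serif;
       margin: 2em; color: #222; }
h1 { font-size: 1.4em; } h2 { font-size: 1.1em; margin-bottom: 0.2em; }
.coords { color: #666; font-size: 0.85em; margin-top: 0; }
table.grid { border-collapse: collapse; margin: 0.6em 0 1.6em; }
table.grid th, table.grid td { padding: 2px 7px; text-align: center;
       font-size: 0.85em; border: 1px solid #e4e4e4; }
td.meth { background: #1a1a1a; color: #fff; }
td.unmeth { background: #fff; color: #999; }
td.missing { background: #f2f2f2; color: #bbb; }
td.num { text-align: right; font-variant-numeric: tabular-nums; }
tr.track td { background: #eef4fb; color: #345; font-size: 0.75em; }
.notice { background: #fff6df; border: 1px solid #e0c97f; padding: 0.5em 0.8em;
          display: inline-block; }
.qc { background: #f4f9f4; border: 1px solid #bcd8bc; padding: 0.6em 1em;
      display: inline-block; margin-bottom: 1.5em; }
"""


def _grid_section(s: PatternSummary) -> List[str]:
    a = s.amplicon
    out = [f"<section id=\"amp-{escape(a.name)}\">",
           f"<h2>{escape(a.name)}</h2>",
           # displayed browser-style (1-based inclusive)
           f"<p class=\"coords\">{escape(a.chrom)}:{a.start + 1}-{a.end} "
           f"&middot; {s.total_reads} reads kept, {s.dropped_reads} dropped</p>"]
    if not s.sites:
        out.append("<p class=\"notice\">No CpG sites observed in this amplicon "
                   "&mdash; every cytosine read as converted.</p>")
        out.append("</section>")
        return out
    out.append("<table class=\"grid\">")
    head = "".join(f"<th>{p + 1}</th>" for p in s.sites)
    out.append(f"<thead><tr><th>pattern</th>{head}<th>reads</th><th>%</th></tr></thead>")
    out.append("<tbody>")
    cls = {"1": "meth", "0": "unmeth", "-": "missing"}
    sym = {"1": "&#9679;", "0": "&#9675;", "-": "&middot;"}
    for r in s.rows:
        cells = "".join(f"<td class=\"{cls[ch]}\">{sym[ch]}</td>" for ch in r.pattern)
        out.append(
            f"<tr><td>{escape(r.pattern)}</td>{cells}"
            f"<td class=\"num\">{r.count}</td>"
            f"<td class=\"num\">{100 * r.fraction:.4f}</td></tr>"
        )
    out.append("</tbody>")
    track = "".join(
        "<td>&ndash;</td>" if f is None else f"<td>{100 * f:.1f}%</td>"
        for f in s.site_meth_fraction
    )
    out.append(f"<tfoot><tr class=\"track\"><td>site % meth</td>{track}"
               f"<td></td><td></td></tr></tfoot>")
    out.append("</table></section>")
    return out


def render_html(
    summaries: Iterable[PatternSummary],
    qc: QCReport,
    path: Union[str, Path],
) -> None:
    """Render the self-contained HTML report for one sample.

    Everything needed to redraw or re-analyze the figure is embedded in a
    ``<script type="application/json">`` data island; no network access or
    external assets are required to view the file.
    """
    summaries = list(summaries)
    sample = summaries[0].sample_name if summaries else qc.sample_name
    island = json.dumps(
        {"format": TSV_FORMAT_VERSION,
         "sample": sample,
         "summaries": [summary_to_dict(s) for s in summaries],
         "qc": qc_to_dict(qc)},
        separators=(",", ":"),
    ).replace("<", "\\u003c")
    conv = (f"{100 * qc.conversion_rate:.4f}% of non-CpG cytosines converted"
            if qc.conversion_defined
            else "undefined (no non-CpG calls observed)")
    parts = [
        "<!DOCTYPE html>",
        "<html lang=\"en\"><head><meta charset=\"utf-8\"/>",
        f"<title>Methylation patterns &mdash; {escape(sample)}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>DNA methylation patterns: {escape(sample)}</h1>",
        f"<p>Generated by amplimeth {__version__}. Each grid row is one "
        "epiallele (per-molecule methylation pattern); "
        "&#9679; methylated, &#9675; unmethylated, &middot; not covered.</p>",
        "<div class=\"qc\"><strong>Bisulfite conversion QC:</strong> "
        f"{conv}; malformed records: {qc.malformed_records}; "
        f"call conflicts: {qc.call_conflicts}</div>",
    ]
    for s in summaries:
        parts.extend(_grid_section(s))
    parts.append(
        f"<script type=\"application/json\" id=\"{DATA_ISLAND_ID}\">{island}</script>"
    )
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts) + "\n", encoding="utf-8")


def extract_html_data(
    source: Union[str, Path],
) -> Tuple[List[PatternSummary], QCReport]:
    """Recover the embedded summaries and QC report from a rendered HTML file."""
    text = Path(source).read_text(encoding="utf-8")
    marker = f"id=\"{DATA_ISLAND_ID}\">"
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    payload = json.loads(text[start:end])
    return ([summary_from_dict(d) for d in payload["summaries"]],
            qc_from_dict(payload["qc"]))
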