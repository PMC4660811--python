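# amplimeth

Epiallele pattern counting and visualization for targeted (multiplex PCR)
bisulfite amplicon sequencing.

## The problem

Bisulfite sequencing reads report the methylation state of every cytosine on
a single DNA molecule. Most analyses immediately average those calls into a
per-CpG methylation percentage — a summary that destroys allelic structure:
an amplicon at 50 % average methylation may be a homogeneous population of
half-methylated molecules, or a 50/50 mixture of fully methylated and fully
unmethylated epialleles, and the per-site average cannot tell the two apart.

`amplimeth` works at the molecule level. For each PCR amplicon it writes the
ordered CpG states of each read as a string over `1` (methylated), `0`
(unmethylated) and `-` (site not covered) — the read's **epiallele** — and
counts the distinct strings. For an amplicon with sites
$s_1 < s_2 < \dots < s_k$ and $N$ kept reads, the output is the set of
observed patterns $p$ with counts $n_p$ ($\sum_p n_p = N$), their fractions
$n_p / N$, and the per-site methylation level
$m_i = \frac{\#\{\text{kept reads methylated at } s_i\}}{\#\{\text{kept reads covering } s_i\}}$
for cross-checking against conventional summaries.

It is aimed at targeted designs: a panel of bisulfite PCR amplicons
(promoters, imprinted loci, repeats, mitochondrial sequence) sequenced
deeply on a short-read instrument, aligned with a bisulfite-aware aligner,
and reduced to per-cytosine calls by the Bismark methylation extractor. The
package operates strictly downstream of the extractor: alignment and
extraction are not reimplemented here.

## Inputs and outputs

Inputs:

1. **Bismark methylation-extractor files** (plain or gzip): one tab-separated
   line per cytosine call — read id, `+`/`-` state, chromosome, 1-based
   position, context letter (`Z/z` CpG, `X/x` CHG, `H/h` CHH).
2. **A BED-like amplicon config**: chrom, start, end, name, forward- and
   reverse-primer length per line. Primer-covered bases carry primer (not
   template) methylation signal, so CpG scoring is restricted to the
   primer-trimmed interior of each amplicon. Coordinates may be BED-style
   (0-based half-open) or browser-style (1-based closed, `--coordinate-style
   ucsc`).
3. Optionally a tab-separated **sample manifest** (name, description,
   accession).

Outputs, per sample:

- `<sample>.patterns.tsv` — one row per (amplicon, epiallele) with read
  count and fraction, plus metadata lines that make the file losslessly
  re-parseable;
- `<sample>.html` — a single self-contained report (no network assets): per
  amplicon, a grid of patterns ranked by abundance with a per-site
  methylation track, plus a bisulfite-conversion QC panel; the underlying
  numbers are embedded as a JSON data island;
- `<sample>.qc.tsv` — conversion-efficiency QC: the fraction of non-CpG
  cytosines (CHG+CHH) read as unmethylated, which should be near 1.0 after
  successful bisulfite treatment.

The package ships a transcription of the 48-amplicon multiplex panel and
86-sample manifest of the study design it models (see
`amplimeth.resources`), including a no-CpG control amplicon used to verify
conversion.

## Worked example

Simulate a sample from a declared epiallele mixture and summarize it against
the packaged panel. The demo spec draws 10 000 reads for the `mandatory01`
amplicon (3 CpG sites) from the mixture 60 % `111`, 30 % `010`, 10 % `000`,
4 000 reads for `h19` from 50 % `1111` / 50 % `0000` (an imprinted-locus
pattern), and 10 000 non-CpG calls with 1 % conversion error:

```
amplimeth simulate --spec src/amplimeth/data/demo_simspec.json --out demo/
amplimeth summarize \
    --amplicons src/amplimeth/data/multiplex_panel_amplicons.tsv \
    --extractor demo/demo_simspec.extractor.txt \
    --sample demo --out demo/ --strand-mode forward
```

`demo/demo.patterns.tsv` then contains (data rows only):

```
demo  mandatory01  chr4   154710459  154710544  3  154710490;154710497;154710504  111   6051  0.605100
demo  mandatory01  chr4   154710459  154710544  3  154710490;154710497;154710504  010   2974  0.297400
demo  mandatory01  chr4   154710459  154710544  3  154710490;154710497;154710504  000    975  0.097500
demo  h19          chr11  2017872    2018050    4  2017910;2017917;2017924;2017931  1111  2042  0.510500
demo  h19          chr11  2017872    2018050    4  2017910;2017917;2017924;2017931  0000  1958  0.489500
```

The estimated pattern fractions (0.6051 / 0.2974 / 0.0975) recover the
generating mixture to within binomial sampling error, and because the demo
uses no site dropout the counts equal the simulator's truth table exactly.
`demo/demo.qc.tsv` reports `conversion_rate 0.989100` — the estimate of the
simulated 99 % conversion efficiency — and `demo/demo.html` shows both
pattern grids plus a "No CpG sites" notice for the `uniq_noCG_1` control.

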