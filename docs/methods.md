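# Methods

## Procedure

`amplimeth` summarizes targeted bisulfite sequencing at the level of single
molecules. The computation, per sample:

1. **Call parsing.** Bismark methylation-extractor files are streamed one
   record at a time (memory bounded by a single record). Each line carries a
   read id, a `+`/`-` methylation state, a chromosome, a 1-based position and
   a context letter (`Z/z` CpG, `X/x` CHG, `H/h` CHH, `U/u` unknown).
   Positions are converted to 0-based. Lines whose state symbol disagrees
   with the letter's case are internally inconsistent; they are skipped and
   counted in the QC report rather than aborting the run. A wrong column
   count is a hard error naming the line.
2. **Strand collapse.** A CpG dinucleotide is one methylation unit spanning
   both strands, but original-bottom-strand reads report it at the G, one
   base right of the forward-strand C. Reverse-strand CpG calls are shifted
   −1 so both strands accumulate on the same site.
3. **Site discovery.** Each amplicon's CpG site list is the sorted union of
   observed CpG call positions inside its primer-trimmed interval
   `[start + fwd_primer_len, end − rev_primer_len)`. Discovery is empirical —
   no reference FASTA is consulted — because the tool's inputs are exactly
   the extractor file and the amplicon config. A reference-derived site map
   is a possible extension point, not implemented. An empty site list is
   legal and expected for a no-CpG control amplicon.
4. **Pattern assembly.** For every read with at least one call on an
   amplicon's sites, the ordered states form a string over `1`/`0`/`-`
   (methylated / unmethylated / site not covered). Duplicate calls for one
   (read, site) — overlapping mate pairs — are resolved first-seen-wins;
   disagreeing duplicates increment a conflict counter in QC. A read
   overlapping two amplicons contributes independently to each.
5. **Counting.** Reads covering fewer than `min_coverage_fraction` of the
   sites are dropped (and reported). Identical strings are aggregated and
   ranked by count descending, ties broken lexicographically ascending —
   a total order, so output is deterministic and independent of input record
   order. Per-site methylation fractions are computed over covering kept
   reads only; a site covered by no kept read reports no value rather than a
   fabricated 0.
6. **Conversion QC.** Bisulfite converts unmethylated cytosine to uracil;
   since mammalian non-CpG methylation is negligible in most tissues,
   methylated CHG/CHH calls estimate conversion failure. The QC report gives
   `conversion_rate = unmethylated non-CpG calls / all non-CpG calls` with a
   per-context breakdown, and flags the rate undefined when no non-CpG calls
   exist.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage_fraction` | 1.0 | fraction of an amplicon's sites a read must cover to be counted. The default keeps only full-length epialleles — the directly interpretable molecules; lower values retain `-`-containing strings as distinct patterns. |
| `coordinate_style` | `bed` | amplicon config coordinates: `bed` = 0-based half-open, `ucsc` = 1-based fully closed (browser spans). Internally everything is 0-based half-open; converting once at input prevents off-by-one drift. |
| `strand_mode` | `auto` | `auto`: infer each file's bisulfite strand from Bismark's OT/OB filename tokens, falling back to positions as reported with a logged warning; `forward`: use positions as reported; `collapse`: require an inferable strand per file and shift reverse CpG calls −1. The choice exists because strand provenance is a property of the extractor invocation, not of the call lines themselves. |
| primer lengths | per config | bases excluded from each amplicon end; CpGs under primers carry primer sequence, not template methylation. Absent columns default to 0 with a warning so plain 4-column BED works. |

## Synthetic data generator

The simulator emulates the data a targeted experiment hands the counter:
for each amplicon it draws `n_reads` epialleles from a declared
pattern-frequency map, applies independent per-site dropout
(`dropout_rate`), and emits one extractor line per surviving call; it adds
`n_noncpg` CHG/CHH calls methylated with probability `conversion_error`,
spread over non-CpG positions of the amplicons. It writes a truth table of
drawn epiallele counts. All randomness comes from one seeded NumPy PCG64
generator (named in the output metadata), so a fixed spec is byte-reproducible.

Packaged defaults (the demo spec) reflect a realistic amplicon experiment:
deep coverage (10⁴ reads on the main amplicon), no site dropout — amplicon
reads span the whole target, so a read normally reports every site — and
1 % conversion error, matching the high conversion efficiency a successful
bisulfite treatment achieves. The generator does **not** model sequencing
error, alignment artifacts, chimeric PCR products, or PCR amplification
bias. Passing recovery tests therefore demonstrates correctness of the
counting machinery, not robustness to upstream artifacts: on real data,
pattern counts inherit whatever biases PCR and alignment introduce.

## Numerical and design choices

- **Tie-breaks** in ranking are lexicographic on the pattern string; with
  counts this gives a total order and byte-identical reruns.
- **Fractions** are exact integer ratios evaluated in double precision; the
  TSV prints 6 decimals, the HTML 4-decimal percentages, and both round-trip
  readers recompute from the integer counts rather than re-parsing printed
  floats, so write→parse reproduces summaries bit-for-bit.
- **Degenerate inputs** are not errors: an empty extractor file, an amplicon
  with no overlapping calls, and the no-CpG control all produce valid,
  empty-but-labelled output.
- **Unknown-context (`U/u`) calls** are parsed but excluded from both
  patterns and QC.
- **Packaged fixtures.** The shipped amplicon panel and sample manifest
  transcribe a real 48-amplicon / 86-sample multiplex design. Rows whose
  genomic span (16 amplicons) or entire content (one amplicon, one sample)
  could not be recovered from the source material carry documented
  placeholders, flagged in the fixture file headers; the parser itself
  rejects span-less lines, so placeholders are explicit data, never silent
  invention. Primer lengths are locus-specific lengths (printed primers
  minus the 33/34 nt Illumina Nextera adapter tails).
- **HTML output** is dependency-free static markup with an embedded JSON
  data island — viewable offline, archivable, and machine-recoverable. The
  missing state (`-`) is rendered as a third visual state rather than
  hidden, so partial reads stay visible at lower coverage thresholds.

## Limitations

- CpG sites are discovered from observed calls, so a site unmethylated in
  every read is still discovered (unmethylated calls are calls), but a site
  covered by zero reads is invisible; site numbering can differ between
  samples with disjoint coverage.
- Pattern counts are read counts, not molecule counts; PCR duplicates are
  not collapsed (the extractor input carries no UMI information).
- The tool summarizes; it does not test. Differential methylation,
  methylation entropy and co-methylation statistics are downstream analyses
  outside its scope, as are alignment and genome-scale (WGBS/RRBS)
  processing.
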