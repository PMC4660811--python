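{
  "seed": 20150913,
  "dropout_rate": 0.0,
  "conversion_error": 0.01,
  "n_noncpg": 10000,
  "amplicons": [
    {
      "name": "mandatory01",
      "chrom": "chr4",
      "start": 154710459,
      "end": 154710544,
      "fwd_primer_len": 26,
      "rev_primer_len": 23,
      "sites": [
        154710490,
        154710497,
        154710504
      ],
      "epiallele_freqs": {
        "111": 0.6,
        "010": 0.3,
        "000": 0.1
      },
      "n_reads": 10000
    },
    {
      "name": "h19",
      "chrom": "chr11",
      "start": 2017872,
      "end": 2018050,
      "fwd_primer_len": 33,
      "rev_primer_len": 30,
      "sites": [
        2017910,
        2017917,
        2017924,
        2017931
      ],
      "epiallele_freqs": {
        "1111": 0.5,
        "0000": 0.5
      },
      "n_reads": 4000
    },
    {
      "name": "uniq_noCG_1",
      "chrom": "chr5",
      "start": 11000000,
      "end": 11000120,
      "fwd_primer_len": 27,
      "rev_primer_len": 33,
      "sites": [],
      "epiallele_freqs": {},
      "n_reads": 0
    }
  ]
}
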