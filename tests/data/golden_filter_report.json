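{
  "stages": [
    {
      "name": "input",
      "n": 45,
      "n_snps": 45,
      "n_indels": 0
    },
    {
      "name": "low_index",
      "n": 45,
      "n_snps": 45,
      "n_indels": 0
    },
    {
      "name": "mut_fixed",
      "n": 5,
      "n_snps": 5,
      "n_indels": 0
    },
    {
      "name": "wt_bound",
      "n": 1,
      "n_snps": 1,
      "n_indels": 0
    }
  ],
  "survivors": [
    {
      "chrom": "chr1",
      "pos": 2771134,
      "ref": "C",
      "alt": "T",
      "vclass": "SNP",
      "wt_index": 0.25,
      "mut_index": 1.0
    }
  ]
}
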