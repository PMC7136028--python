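{
  "name": "CRP_promoter_synthetic",
  "cpg_positions": [
    264,
    320,
    442,
    497,
    530
  ],
  "tss_offset": 550,
  "cpg_labels": [
    "-286",
    "-230",
    "-108",
    "-53",
    "-20"
  ],
  "snp": {
    "offset": 264,
    "alleles": [
      "C",
      "A"
    ],
    "label": "-286C/A"
  },
  "provenance": {
    "synthetic": true,
    "note": "Synthetic stand-in for the human CRP promoter (-550 ~ +1 bp window, 551 bp): five CpGs with a C/A SNP-CpG at -286 and a CpG observed/expected ratio of ~0.23; generated, not genomic sequence.",
    "generator": "amplimeth.simulate.simulate_amplicon",
    "call": {
      "length": 551,
      "cpg_offsets": [
        264,
        320,
        442,
        497,
        530
      ],
      "gc_content": 0.3975,
      "seed": 20260929,
      "snp_offset": 264,
      "tss_offset": 550
    },
    "achieved_ratio": 0.2298
  }
}
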