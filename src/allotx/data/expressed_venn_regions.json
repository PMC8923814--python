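{
  "description": "Region cardinalities of the three-way Venn of expressed-gene sets (TPM>0) in the in silico hybrid (A_C), resynthesized allopolyploid (RAC), and natural allopolyploid (NAC) leaf transcriptomes.",
  "regions": {
    "A_C": 3966,
    "RAC": 3515,
    "NAC": 2801,
    "A_C&RAC": 3891,
    "A_C&NAC": 2462,
    "RAC&NAC": 3177,
    "A_C&RAC&NAC": 51949
  }
}
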