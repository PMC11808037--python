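{
  "accession": "NM_006846.4",
  "cds_length": 3195,
  "protein_length": 1064,
  "half_boundary": 1598
}
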