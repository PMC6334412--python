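{
  "HIST": {
    "raw_reads": 28667031,
    "high_quality_reads": 28122819,
    "clean_reads": 27877781,
    "unique_tags": 1066655,
    "mapped_reads": 20847175,
    "mapped_unique_tags": 584229
  },
  "NC": {
    "raw_reads": 21372487,
    "high_quality_reads": 20988298,
    "clean_reads": 20658317,
    "unique_tags": 1056485,
    "mapped_reads": 14488689,
    "mapped_unique_tags": 594634
  }
}
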