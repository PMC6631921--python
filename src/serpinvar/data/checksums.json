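{
  "table2_scores.tsv": "9145ed5313055078593b6b3942706c6098e5dd07b0e5e387c817ac6f99369509",
  "table3_benchmark.tsv": "2159256244c0011a936db87c6abeabba83af6f749d6b4cdc57bacd78a140159c"
}
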