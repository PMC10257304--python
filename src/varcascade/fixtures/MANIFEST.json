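{
  "table1_cohort.tsv": "252f2417d26955f0b08724bed5d37cc25f6c465b76e8e6b8f1370da0de5e313a",
  "table2_counts.tsv": "68e0979dea52d17abd51404e919e335b09a79e85d7debd34e00d211e93bcd619",
  "table3_variants.tsv": "5dd141cc2204eff7fbbb1848d81886859e843fb9d1e4379c49bb2c5dce7dded9",
  "table4_highimpact.tsv": "e677beaadf050d1de6050ad43eb5d7a17d5181d74e67ccbd9923439ead347fce"
}
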