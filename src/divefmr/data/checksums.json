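{
 "table1_energetics.csv": "be540e06009501eb0e65f6842d507fc4db1203b7b939975f8ad924c191b90243",
 "table2_behavior.csv": "992936e97d9276246f4a624151855ce73f0348321c40b3f28cede29c58779aa1"
}
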