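{
  "dinucleotide_properties_synthetic.tsv": "ba691ed8ace73d6ca0543cfb51281494d951049f0a3e32eab97e9bdcb4d1051d",
  "trinucleotide_properties_synthetic.tsv": "7b27e3bed9153b62de0ca08d9bf1512e9d0ff43c1d9a1d5ed3edd6ced72736c7"
}
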