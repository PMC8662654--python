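metric	biofilm	planktonic
cumulative_mutations	535	339
day90_mutations	382	201
fixed_mutations	48	5
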