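pladias_id,fsg_id
1238,14
1444,14
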