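bfl_pid,fsg_id
20111,14
52,14
6539,14
14276,14
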