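source,records
Flora of Bavaria - occurrence data online (volunteer experts),237734
Floristic records from survey studies (state agencies),123439
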