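pid,full_name,category,accepted_pid
20111,Aconitum napellus subsp. lusitanicum Rouy,ACCEPTED,
52,Aconitum napellus L. s. l.,ACCEPTED,
6539,Aconitum napellus L. subsp. napellus,ACCEPTED,
14276,Aconitum plicatum Köhler ex Rchb.,ACCEPTED,
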