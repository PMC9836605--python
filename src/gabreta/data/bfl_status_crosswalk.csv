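code,label,pladias_origin,poss_native,poss_introduced,poss_cultivated
I,indigenous,native,native,not introduced,not cultivated
*,normal status,native,assumed to be native,not introduced,not cultivated
E,established,non-native,not native,introduced,not cultivated
D,permanently established,without equivalent,doubtfully native,assumed to be introduced,not cultivated
U,casual,without equivalent,not native,introduced,not cultivated
T,tendency towards establishment,non-native,not native,introduced,not cultivated
W,re-introduced / naturally casual,without equivalent,native,introduced,not cultivated
K,cultivated,planted,not native,none of the above,cultivated outdoors
S,synanthropic,without equivalent,not native,none of the above,no information
A,deliberately introduced,planted,not native,none of the above,cultivated outdoors
R,culture relic,planted,not native,none of the above,cultivated outdoors
?,status completely unclear,without equivalent,no information,no information,no information
Z,dubious if native,without equivalent,doubtfully native,doubtfully introduced,not cultivated
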