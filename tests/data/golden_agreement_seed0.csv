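rule,flag_extreme,noflag_extreme,flag_not_extreme,noflag_not_extreme,incorrect_rate,correct_rate
BP,9,16,15,208,0.06726457399103139,0.36
SQ,12,13,21,202,0.09417040358744394,0.48
AB,14,11,28,195,0.12556053811659193,0.56
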