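# Published Taiwan single-center blind-test confusion counts
# (418 KD and 259 febrile controls; calls by the two-step algorithm).
true,call,count
KD,KD,379
KD,FC,24
KD,INDETERMINATE,15
FC,KD,30
FC,FC,223
FC,INDETERMINATE,6
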