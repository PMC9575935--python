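# Published correct-call and indeterminate counts by criteria-count stratum.
# "correct" means called KD for the KD rows and called FC for the FC rows.
group,stratum,correct,indeterminate,total
KD,le2,2,1,14
KD,3,16,13,36
KD,ge4,361,1,368
FC,le2,157,1,158
FC,3,56,3,59
FC,ge4,10,2,42
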