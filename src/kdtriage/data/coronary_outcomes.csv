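# Published two-step-algorithm calls for KD patients by coronary-artery
# echocardiogram status. Note: the rows with Z >= 2.5 sum to more patients
# than the stated 44 with abnormal arteries; the printed counts are kept
# as printed. NO_ECHO / DATA_MISSING rows are outside the 44.
status,correct,indeterminate,misclassified
NORMAL,309,10,12
DILATED,30,0,1
ANEURYSM,8,0,0
UNRESOLVED,12,0,0
NO_FOLLOWUP,1,0,0
DATA_MISSING,10,0,0
NO_ECHO,9,5,11
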