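# Published enrollment flow: 751 enrolled (462 KD, 289 FC); 26 FC removed
# for fever-day registration errors before filtering; 47 excluded for fever
# longer than 10 days; 1 FC excluded for having no principal criterion.
stage,kd,fc
enrolled,462,289
registration_error_excluded,0,26
fever_gt_10d_excluded,44,3
no_criteria_excluded,0,1
retained,418,259
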