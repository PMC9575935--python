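# Published distribution of the five principal clinical signs by
# criteria-count stratum (<=2, 3, >=4) in the Taiwan cohort, with the
# printed two-sided Fisher p-value for each KD-vs-FC comparison.
stratum,sign,kd_pos,kd_total,fc_pos,fc_total,printed_p
le2,oropharyngeal_changes,4,14,135,158,<0.001
le2,conjunctival_injection,10,14,5,158,<0.001
le2,cervical_lymphadenopathy,3,14,42,158,1
le2,extremity_changes,3,14,9,158,0.061
le2,rash,8,14,102,158,0.58
3,oropharyngeal_changes,27,36,51,59,0.158
3,conjunctival_injection,29,36,12,59,<0.001
3,cervical_lymphadenopathy,6,36,44,59,<0.001
3,extremity_changes,19,36,21,59,0.1
3,rash,27,36,49,59,0.341
ge4,oropharyngeal_changes,357,368,37,42,0.017
ge4,conjunctival_injection,357,368,34,42,<0.001
ge4,cervical_lymphadenopathy,168,368,42,42,<0.001
ge4,extremity_changes,355,368,22,42,<0.001
ge4,rash,353,368,40,42,0.689
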