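# Published per-age-bin calls for the 418 KD patients
# (140+10+7 = 157 infants; 239+14+8 = 261 older children).
stratum,correct,misclassified,indeterminate,total
<1 year,140,10,7,157
>=1 year,239,14,8,261
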