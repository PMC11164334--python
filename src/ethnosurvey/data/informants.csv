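informant_id,age,gender
I01,28,female
I02,31,male
I03,33,female
I04,35,male
I05,38,female
I06,40,male
I07,43,female
I08,46,male
I09,49,female
I10,52,male
I11,55,female
I12,58,male
I13,60,female
I14,62,male
I15,65,female
I16,68,male
I17,71,female
I18,74,male
I19,77,female
I20,79,male
I21,81,female
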