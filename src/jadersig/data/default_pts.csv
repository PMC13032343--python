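pt_name,pt_code
Appetite disorder,10060961
Decreased appetite,10061428
Abnormal loss of weight,10000159
Ageusia,10001480
Dysgeusia,10013911
Hypogeusia,10020989
Taste disorder,10082490
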