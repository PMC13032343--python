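case_id,version,pt_name,pt_code
C01,1,Decreased appetite,10061428
C01,2,Decreased appetite,10061428
C02,1,Decreased appetite,10061428
C02,1,Nausea,10028813
C03,1,Dysgeusia,10013911
C04,1,Nausea,10028813
C05,1,Decreased appetite,10061428
C06,1,Nausea,10028813
C07,1,Decreased appetite,10061428
C08,1,Decreased appetite,10061428
C09,1,Dysgeusia,10013911
C10,1,Decreased appetite,10061428
C11,1,Decreased appetite,10061428
C12,1,Decreased appetite,10061428
C12,1,Dysgeusia,10013911
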