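case_id,version,drug_seq,role,drug_name
C01,1,1,suspected,alpha
C01,1,2,concomitant,beta
C01,2,1,suspected,alpha
C01,2,2,concomitant,beta
C02,1,1,suspected,alpha
C03,1,1,suspected,alpha
C03,1,2,suspected,gamma
C04,1,1,suspected,beta
C05,1,1,suspected,beta
C05,1,2,interacting,alpha
C06,1,1,suspected,gamma
C07,1,1,suspected,alpha
C07,1,2,suspected,alpha
C08,1,1,concomitant,alpha
C09,1,1,suspected,delta
C10,1,1,suspected,alpha
C11,1,1,suspected,alpha
C12,1,1,suspected,gamma
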