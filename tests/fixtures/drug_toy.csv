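case_id,version,drug_seq,role,drug_name
A1,1,1,suspected,alpha
A1,1,2,concomitant,beta
A1,2,1,suspected,alpha
A1,2,2,concomitant,beta
A2,1,1,suspected,gamma
A2,1,2,interacting,alpha
A3,1,1,concomitant,beta
A4,1,1,suspected,alpha
A5,1,1,suspected,delta
A5,1,2,suspected,delta
A6,1,1,suspected,beta
A7,1,1,suspected,alpha
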