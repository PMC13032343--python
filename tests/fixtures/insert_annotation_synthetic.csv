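drug_name,appetite_listed,taste_listed
app01,true,false
app02,true,false
app03,true,false
app04,true,false
app05,true,false
app06,true,false
app07,true,false
app08,true,false
app09,true,false
app10,true,false
app11,true,false
app12,true,false
app13,true,false
app14,true,false
app15,true,false
app16,false,false
app17,false,false
app18,false,false
app19,false,false
app20,false,false
taste01,false,true
taste02,false,true
taste03,false,true
taste04,false,true
taste05,false,true
taste06,false,false
taste07,false,false
taste08,false,false
taste09,false,false
taste10,false,false
taste11,false,false
taste12,false,false
taste13,false,false
taste14,false,false
taste15,false,false
taste16,false,false
taste17,false,false
taste18,false,false
taste19,false,false
taste20,false,false
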