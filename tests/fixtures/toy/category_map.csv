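drug_name,category_code,category_label
alpha,119,Other agents affecting central nervous system
beta,421,Antineoplastics - alkylating agents
gamma,625,Anti-virus agents
delta,235,Agents for peptic ulcer
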