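item,term,frequency_weight
S1,loss of interest,1
S1,no pleasure in things,1
S1,nothing excites me anymore,1
S2,feeling down,1
S2,hopeless,1
S2,depressed,1
S3,trouble sleeping,1
S3,insomnia,1
S3,sleeping too much,1
S4,feeling tired,1
S4,no energy,1
S4,exhausted,1
S5,poor appetite,1
S5,overeating,1
S5,no desire to eat,1
S6,feeling like a failure,1
S6,worthless,1
S6,disappointed in myself,1
S7,trouble concentrating,1
S7,cannot focus,1
S7,mind keeps wandering,1
S8,moving slowly,1
S8,restless,1
S8,fidgety,1
S9,better off dead,1
S9,thoughts of hurting myself,1
S9,suicidal thoughts,1
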