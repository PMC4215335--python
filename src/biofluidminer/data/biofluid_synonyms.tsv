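# canonical biofluid name <TAB> synonym (one pair per line, editable)
bile	biliary fluid
blood	whole blood
breastmilk	breast milk
breastmilk	human milk
cerebrospinal fluid	CSF
cerebrospinal fluid	spinal fluid
mucus	sputum
mucus	mucous
plasma	blood plasma
saliva	salivary fluid
semen	seminal fluid
semen	seminal plasma
serum	blood serum
synovial fluid	SF
synovial fluid	joint fluid
stool	feces
stool	faeces
sweat	perspiration
tears	tear fluid
tears	lacrimal fluid
urine	urinary
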