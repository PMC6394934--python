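analyte	age_min	age_max	lower	upper
Uracil	0	18		30.0
Dihydrouracil	0	1		34.0
Dihydrouracil	1	18		12.0
Thymine	0	18		1.2
Dihydrothymine	0	18		6.0
Beta-Ureidopropionic acid	0	1		32.0
Beta-Ureidopropionic acid	1	18		12.0
Adenine	0	18		1.0
Hypoxanthine	0	18		52.0
Allopurinol	0	18		n.d.
Beta-Ureidoisobutyric acid	0	1		9.0
Beta-Ureidoisobutyric acid	1	18		2.5
Xanthine	0	1		43.0
Xanthine	1	18		31.0
2,8-Dihydroxyadenine	0	18		4.0
Deoxyadenosine	0	18		1.0
AICAr	0	18		1.1
Adenosine	0	18		2.0
5-Hydroxymethyluracil	0	18		1.0
Orotic acid	0	18		4.0
Deoxyuridine	0	18		3.0
Thymidine	0	18		1.0
Pseudouridine	0	1	37.0	110.0
Pseudouridine	1	18	30.0	110.0
Deoxyinosine	0	18		1.0
Deoxyguanosine	0	18		1.0
Inosine	0	3		5.0
Inosine	3	18		2.0
Guanosine	0	18		1.0
Orotidine	0	18		4.7
SAICAr	0	18		0.8
Succinyladenosine	0	18		5.0
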