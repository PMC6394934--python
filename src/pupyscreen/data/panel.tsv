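analyte	class	is_internal_standard	internal_standard	esi_mode	role	parent_mz	daughter_mz	cone_v	collision_v	retention_time_min
Uracil	pyrimidine	false	Uracil-IS	positive	quantifier	113.0	70.0	50	14	2.000
Uracil	pyrimidine	false	Uracil-IS	positive	qualifier	113.0	96.1	50	14	2.000
Dihydrouracil	pyrimidine	false	Dihydrouracil-IS	positive	quantifier	115.0	55.0	40	15	2.320
Dihydrouracil	pyrimidine	false	Dihydrouracil-IS	positive	qualifier	115.0	73.0	40	10	2.320
Uracil-IS	pyrimidine	true		positive	quantifier	115.1	71.0	30	14	2.000
Uracil-IS	pyrimidine	true		positive	qualifier	115.1	97.1	30	14	2.000
Dihydrouracil-IS	pyrimidine	true		positive	quantifier	121.0	58.0	40	16	2.320
Dihydrouracil-IS	pyrimidine	true		positive	qualifier	121.0	77.0	40	12	2.320
Thymine	pyrimidine	false	Thymine-IS	positive	quantifier	127.0	110.0	50	16	2.575
Thymine	pyrimidine	false	Thymine-IS	positive	qualifier	127.0	84.1	50	14	2.575
Dihydrothymine	pyrimidine	false	Dihydrothymine-IS	positive	quantifier	129.0	112.0	34	10	2.830
Dihydrothymine	pyrimidine	false	Dihydrothymine-IS	positive	qualifier	129.0	69.0	34	14	2.830
Thymine-IS	pyrimidine	true		positive	quantifier	131.1	114.1	40	15	2.575
Thymine-IS	pyrimidine	true		positive	qualifier	131.1	88.1	40	16	2.575
Beta-Ureidopropionic acid	pyrimidine	false	Uracil-IS	positive	quantifier	133.0	90.1	20	8	3.084
Beta-Ureidopropionic acid	pyrimidine	false	Uracil-IS	positive	qualifier	133.0	72.2	20	12	3.084
Dihydrothymine-IS	pyrimidine	true		positive	quantifier	135.1	74.1	30	14	2.830
Dihydrothymine-IS	pyrimidine	true		positive	qualifier	135.1	90.1	30	13	2.830
Beta-Ureidoisobutyric acid	pyrimidine	false	Uracil-IS	positive	quantifier	147.0	86.0	24	14	4.169
Beta-Ureidoisobutyric acid	pyrimidine	false	Uracil-IS	positive	qualifier	147.0	129.0	24	8	4.169
5-Hydroxymethyluracil	pyrimidine	false	Orotic Acid-IS	negative	quantifier	141.0	123.1	42	12	5.697
5-Hydroxymethyluracil	pyrimidine	false	Orotic Acid-IS	negative	qualifier	141.0	42.0	42	14	5.697
Orotic acid	pyrimidine	false	Orotic Acid-IS	negative	quantifier	155.0	111.0	34	10	5.952
Orotic acid	pyrimidine	false	Orotic Acid-IS	negative	qualifier	155.0	42.0	34	20	5.952
Orotic Acid-IS	pyrimidine	true		negative	quantifier	157.1	113.1	30	10	5.952
Orotic Acid-IS	pyrimidine	true		negative	qualifier	157.1	43.1	30	20	5.952
Deoxyuridine	pyrimidine	false	Guanosine-IS	negative	quantifier	227.0	184.1	44	12	6.207
Deoxyuridine	pyrimidine	false	Guanosine-IS	negative	qualifier	227.0	94.1	44	22	6.207
Thymidine	pyrimidine	false	Thymidine-IS	negative	quantifier	241.1	42.0	44	12	6.462
Thymidine	pyrimidine	false	Thymidine-IS	negative	qualifier	241.1	151.1	44	10	6.462
Pseudouridine	pyrimidine	false	Orotic Acid-IS	negative	quantifier	243.0	153.1	36	12	6.717
Pseudouridine	pyrimidine	false	Orotic Acid-IS	negative	qualifier	243.0	183.1	36	14	6.717
Thymidine-IS	pyrimidine	true		negative	quantifier	253.1	160.1	30	10	6.462
Thymidine-IS	pyrimidine	true		negative	qualifier	253.1	44.1	30	12	6.462
Orotidine	pyrimidine	false	Orotic Acid-IS	negative	quantifier	287.1	111.1	20	15	7.990
Orotidine	pyrimidine	false	Orotic Acid-IS	negative	qualifier	287.1	42.1	20	22	7.990
Adenine	purine	false	Xanthine-IS	positive	quantifier	136.0	92.0	66	24	3.339
Adenine	purine	false	Xanthine-IS	positive	qualifier	136.0	119.1	66	20	3.339
Hypoxanthine	purine	false	Hypoxanthine-IS	positive	quantifier	137.1	110.1	42	18	3.594
Hypoxanthine	purine	false	Hypoxanthine-IS	positive	qualifier	137.1	81.9	42	18	3.594
Allopurinol	purine	false	Hypoxanthine-IS	positive	quantifier	137.1	54.1	56	22	3.914
Allopurinol	purine	false	Hypoxanthine-IS	positive	qualifier	137.1	110.0	56	18	3.914
Hypoxanthine-IS	purine	true		positive	quantifier	142.0	114.1	40	20	3.594
Hypoxanthine-IS	purine	true		positive	qualifier	142.0	124.1	40	20	3.594
Xanthine	purine	false	Xanthine-IS	positive	quantifier	153.1	110.1	26	18	4.423
Xanthine	purine	false	Xanthine-IS	positive	qualifier	153.1	136.0	26	12	4.423
Xanthine-IS	purine	true		positive	quantifier	155.1	137.1	20	14	4.423
2,8-Dihydroxyadenine	purine	false	Xanthine-IS	positive	quantifier	168.1	125.0	66	18	4.678
2,8-Dihydroxyadenine	purine	false	Xanthine-IS	positive	qualifier	168.1	150.8	66	18	4.678
Deoxyadenosine	purine	false	Guanosine-IS	positive	quantifier	252.1	119.0	18	38	4.933
Deoxyadenosine	purine	false	Guanosine-IS	positive	qualifier	252.1	136.1	18	16	4.933
AICAr	purine	false	Guanosine-IS	positive	quantifier	259.2	110.1	26	22	5.188
AICAr	purine	false	Guanosine-IS	positive	qualifier	259.2	127.1	26	10	5.188
Adenosine	purine	false	Guanosine-IS	positive	quantifier	268.2	119.0	30	44	5.443
Adenosine	purine	false	Guanosine-IS	positive	qualifier	268.2	136.1	30	18	5.443
Guanosine-IS	purine	true		positive	quantifier	289.1	139.1	20	40	7.736
Guanosine-IS	purine	true		positive	qualifier	289.1	157.1	20	14	7.736
Deoxyinosine	purine	false	Guanosine-IS	negative	quantifier	251.1	135.1	56	22	6.971
Deoxyinosine	purine	false	Guanosine-IS	negative	qualifier	251.1	161.1	56	24	6.971
Deoxyguanosine	purine	false	Deoxyguanosine-IS	negative	quantifier	266.1	150.0	54	20	7.226
Deoxyguanosine	purine	false	Deoxyguanosine-IS	negative	qualifier	266.1	133.1	54	28	7.226
Inosine	purine	false	Inosine-IS	negative	quantifier	267.1	135.1	58	20	7.481
Inosine	purine	false	Inosine-IS	negative	qualifier	267.1	92.0	58	34	7.481
Inosine-IS	purine	true		negative	quantifier	271.1	139.1	20	20	7.481
Deoxyguanosine-IS	purine	true		negative	quantifier	281.1	160.1	20	20	7.226
Deoxyguanosine-IS	purine	true		negative	qualifier	281.1	142.1	20	30	7.226
Guanosine	purine	false	Guanosine-IS	negative	quantifier	282.1	150.0	48	18	7.736
Guanosine	purine	false	Guanosine-IS	negative	qualifier	282.1	133.1	48	30	7.736
Guanosine-IS	purine	true		negative	quantifier	287.1	155.1	20	18	7.736
Guanosine-IS	purine	true		negative	qualifier	287.1	137.1	20	30	7.736
SAICAr	purine	false	Guanosine-IS	negative	quantifier	373.1	355.1	20	18	8.245
SAICAr	purine	false	Guanosine-IS	negative	qualifier	373.1	294.1	20	20	8.245
Succinyladenosine	purine	false	Guanosine-IS	negative	quantifier	382.1	206.2	40	20	8.500
Succinyladenosine	purine	false	Guanosine-IS	negative	qualifier	382.1	134.1	40	30	8.500
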