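# External quality-control reference results (display fixture, n = 10 instrument runs; not recomputable).
analyte	level_uM	cv_interday_pct	cv_intraday_pct	cv_injection_pct	recovery_pct
Uracil	71.8	3.7	3.0	4.1	105.1
Dihydrouracil	65.1	6.2	4.4	3.6	118.4
Thymine	39.5	3.4	2.5	4.3	107.7
Dihydrothymine	70.5	3.9	3.4	2.7	108.7
Beta-Ureidopropionic acid	n.a.	n.a.	n.a.	n.a.	n.a.
Adenine	28.0	4.8	2.8	2.6	123.8
Hypoxanthine	116.0	4.6	2.9	3.2	94.5
Allopurinol	n.a.	n.a.	n.a.	n.a.	n.a.
Beta-Ureidoisobutyric acid	n.a.	n.a.	n.a.	n.a.	n.a.
Xanthine	95.9	3.9	3.5	3.6	107.1
2,8-Dihydroxyadenine	n.a.	n.a.	n.a.	n.a.	n.a.
Deoxyadenosine	38.0	4.7	4.3	4.3	119.7
AICAr	52.5	5.7	4.0	1.9	94.1
Adenosine	34.8	6.3	4.6	2.7	110.6
5-Hydroxymethyluracil	49.7	8.5	5.9	6.9	103.4
Orotic acid	80.0	4.1	2.3	3.6	97.8
Deoxyuridine	43.1	8.6	3.9	3.2	92.8
Thymidine	22.8	8.8	11.6	9.7	89.4
Pseudouridine	90.3	6.3	2.2	3.1	108.4
Deoxyinosine	38.4	2.6	1.3	3.0	101.3
Deoxyguanosine	37.9	3.0	4.4	3.1	100.5
Inosine	50.0	3.5	2.9	2.8	97.0
Guanosine	56.4	3.4	2.8	2.0	95.7
Orotidine	14.0	5.9	5.4	4.3	82.9
Succinyladenosine	n.a.	n.a.	n.a.	n.a.	n.a.
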