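first	second	note
Uracil-IS	Dihydrouracil	parent ions 115.1/115.0, qualifier daughter 73.0 within 2 Da of IS daughter 71.0
Hypoxanthine	Allopurinol	isobaric parent 137.1, shared ~110 daughter channel
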