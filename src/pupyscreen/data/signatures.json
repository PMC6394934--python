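{
  "ADSL": {
    "name": "Adenylosuccinate lyase deficiency",
    "required_high": ["SAICAr", "Succinyladenosine"],
    "optional_high": [],
    "required_low": [],
    "confound_notes": ""
  },
  "ATIC": {
    "name": "AICAR transformylase/IMP cyclohydrolase deficiency",
    "required_high": ["AICAr"],
    "optional_high": ["SAICAr"],
    "required_low": [],
    "confound_notes": ""
  },
  "APRT": {
    "name": "Adenine phosphoribosyltransferase deficiency",
    "required_high": ["Adenine", "2,8-Dihydroxyadenine"],
    "optional_high": [],
    "required_low": [],
    "confound_notes": ""
  },
  "HGPRT": {
    "name": "Hypoxanthine-guanine phosphoribosyltransferase deficiency",
    "required_high": ["Hypoxanthine"],
    "optional_high": ["Xanthine"],
    "required_low": [],
    "confound_notes": "Orotidine/orotic acid elevations under allopurinol treatment are drug effects, not evidence against this call."
  },
  "UMPS": {
    "name": "Uridine monophosphate synthetase deficiency",
    "required_high": ["Orotidine"],
    "optional_high": ["Orotic acid"],
    "required_low": [],
    "confound_notes": "Orotidine and orotic acid also accumulate under allopurinol treatment; a call requires the drug channel to be clean."
  },
  "UPB1": {
    "name": "Beta-ureidopropionase deficiency",
    "required_high": ["Beta-Ureidopropionic acid", "Beta-Ureidoisobutyric acid"],
    "optional_high": ["Dihydrouracil", "Dihydrothymine"],
    "required_low": [],
    "confound_notes": ""
  },
  "DPD": {
    "name": "Dihydropyrimidine dehydrogenase deficiency",
    "required_high": ["Uracil", "Thymine"],
    "optional_high": [],
    "required_low": [],
    "confound_notes": ""
  },
  "DHP": {
    "name": "Dihydropyrimidinase deficiency",
    "required_high": ["Dihydrouracil", "Dihydrothymine"],
    "optional_high": ["Uracil", "Thymine"],
    "required_low": [],
    "confound_notes": ""
  },
  "TP": {
    "name": "Thymidine phosphorylase deficiency",
    "required_high": ["Thymidine", "Deoxyuridine"],
    "optional_high": [],
    "required_low": [],
    "confound_notes": ""
  },
  "MoCoD": {
    "name": "Molybdenum cofactor deficiency",
    "required_high": ["Xanthine"],
    "optional_high": ["Hypoxanthine"],
    "required_low": [],
    "confound_notes": "Urinary pattern overlaps with isolated xanthine dehydrogenase deficiency; confirmation needs sulfite/S-sulfocysteine testing."
  },
  "ADA": {
    "name": "Adenosine deaminase deficiency",
    "required_high": ["Deoxyadenosine"],
    "optional_high": ["Adenosine"],
    "required_low": [],
    "confound_notes": ""
  },
  "PNP": {
    "name": "Purine nucleoside phosphorylase deficiency",
    "required_high": ["Inosine", "Guanosine"],
    "optional_high": ["Deoxyinosine", "Deoxyguanosine"],
    "required_low": [],
    "confound_notes": ""
  },
  "XDH": {
    "name": "Xanthine dehydrogenase deficiency",
    "required_high": ["Xanthine"],
    "optional_high": ["Hypoxanthine"],
    "required_low": [],
    "confound_notes": "Urinary pattern overlaps with molybdenum cofactor deficiency."
  },
  "PRPPS": {
    "name": "Phosphoribosylpyrophosphate synthetase superactivity",
    "required_high": ["Hypoxanthine", "Xanthine"],
    "optional_high": [],
    "required_low": [],
    "confound_notes": "Overproduction pattern; overlaps with salvage-pathway defects and requires enzymatic confirmation."
  }
}
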