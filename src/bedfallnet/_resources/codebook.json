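{
  "A": "improper use of bed rails",
  "B": "inadequate postoperative nursing education",
  "C": "older adult patients using the toilet alone",
  "D": "improper use of call bells",
  "E": "patient's auditory and visual impairments",
  "F": "sudden change in patient's consciousness",
  "G": "orthostatic hypotension induced by diuretic antihypertensive drugs",
  "H": "poor drug adherence",
  "I": "inadequate monitoring of sedated patients",
  "J": "caregivers failing to notice patient's condition in time",
  "K": "combined use of sedatives and femoral nerve block analgesia pumps",
  "L": "unsuitable bed design",
  "M": "poor collaboration between healthcare providers",
  "N": "using sedative-hypnotic drugs and using the toilet at night",
  "O": "patient's cognitive and communication impairments",
  "P": "lower limb weakness caused by femoral nerve block analgesia pumps",
  "Q": "irregular use of antiepileptic drugs",
  "R": "impaired consciousness not being effectively managed",
  "S": "caregiver absence leading to care deficiency",
  "T": "caregivers not assisting patients in time",
  "U": "getting out of bed without assistance after using sedative-hypnotic and analgesic drugs",
  "V": "non-slip resistant slippers"
}
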