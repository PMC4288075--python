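query,expected_display_name
alvarex,Maria Alvarez
carrie tull,Carie Tull
Ceasar gonzaga,Caesar Gonzaga
phillip zickerman,Philip Zickerman
reinhardt,Richard Reinhart
roedrick koehler,Roderick Koehler
rousch,Stephen Roush
scott erickwon,Scott Erickson
STEVEN TOOTHACKER,Stephen Toothaker
tim swan,Timothy Swan
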