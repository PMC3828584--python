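# Domain architecture of human myosin XVa (unconventional myosin 15,
# MYO15A / DFNB3), 1-based inclusive residue intervals. The SH3 domain
# overlaps the end of the first FERM domain; overlaps are preserved.
protein: MYO15A
domains:
  - {name: N-terminal, start: 1, end: 1223}
  - {name: motor, start: 1224, end: 1899}
  - {name: IQ, start: 1909, end: 1942}
  - {name: MyTH4a, start: 2066, end: 2174}
  - {name: FERMa, start: 2687, end: 2867}
  - {name: SH3, start: 2865, end: 2959}
  - {name: MyTH4b, start: 3051, end: 3161}
  - {name: FERMb, start: 3217, end: 3497}
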