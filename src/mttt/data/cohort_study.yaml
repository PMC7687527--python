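# Per-variant carrier counts observed in the published MT-TT screen:
# 352 LHON cases, 376 controls, 15 distinct variants in cases, 7 in
# controls, one variant per carrier.  These counts are the study
# conditions the synthetic cohort reproduces exactly.
n_cases: 352
n_controls: 376
implants:
  - {variant: m.15927G>A, cases: 8, controls: 0}
  - {variant: m.15951A>G, cases: 4, controls: 0}
  - {variant: m.15900T>C, cases: 1, controls: 1}
  - {variant: m.15901A>G, cases: 1, controls: 0}
  - {variant: m.15908T>C, cases: 1, controls: 1}
  - {variant: m.15924A>G, cases: 9, controls: 3}
  - {variant: m.15928G>A, cases: 3, controls: 2}
  - {variant: m.15931A>C, cases: 1, controls: 0}
  - {variant: m.15940DelT, cases: 1, controls: 0}
  - {variant: m.15943T>C, cases: 2, controls: 1}
  - {variant: m.15949G>A, cases: 1, controls: 0}
  - {variant: m.15907A>G, cases: 1, controls: 0}
  - {variant: m.15930G>A, cases: 2, controls: 13}
  - {variant: m.15938C>T, cases: 1, controls: 0}
  - {variant: m.15941T>C, cases: 5, controls: 2}
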