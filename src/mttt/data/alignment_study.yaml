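# Per-site species match counts for the 44-vertebrate tRNA-Thr
# alignment (human included; human always matches itself).  Keys are
# tRNAdb positions; values are the number of species whose base matches
# the human base, chosen so that 100*k/44 reproduces the published
# conservation index at each variant site.  Unlisted positions default
# to full conservation (44/44).
#
# Site 42 is listed with k=33 (CI 75.00): the published value 75.45 is
# not expressible as k/44 and is treated as a typographical artefact.
n_species: 44
match_counts:
  13: 32
  14: 44
  22: 29
  23: 41
  39: 40
  42: 33
  43: 34
  45: 11
  46: 43
  54: 18
  56: 10
  61: 21
  63: 35
  69: 39
  71: 31
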