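# Minimal curated mtDNA haplogroup tree for Eastern Asian lineages.
#
# Each node lists the variants (differences from rCRS) that define the
# branch leading to it from its parent; a lineage's full motif is the
# union along the root->node path.  rCRS itself (an H2a2a1 molecule) is
# the root, so the ubiquitous non-H basal substitutions hang off the N
# node and the macrohaplogroup M motif nests under it.  This is a
# deliberately small, replaceable stand-in for a full PhyloTree import:
# branch motifs follow the well-known defining variants where practical
# but the tree is curated, not exported from any database.
root: rCRS
nodes:
  rCRS: {parent: null, variants: []}
  H2: {parent: rCRS, variants: [m.195T>C, m.16232C>A]}
  N:
    parent: rCRS
    variants: [m.73A>G, m.263A>G, m.750A>G, m.1438A>G, m.2706A>G, m.4769A>G,
               m.7028C>T, m.8860A>G, m.11719G>A, m.14766C>T, m.15326A>G]
  M:
    parent: N
    variants: [m.489T>C, m.8701A>G, m.9540T>C, m.10398A>G, m.10400C>T,
               m.10873T>C, m.14783T>C, m.15043G>A, m.15301G>A, m.16223C>T]
  D: {parent: M, variants: [m.4883C>T, m.5178C>A]}
  D4: {parent: D, variants: [m.3010G>A, m.8414C>T, m.14668C>T]}
  D4e1a: {parent: D4, variants: [m.3316G>A, m.9536C>T, m.16092T>C]}
  G: {parent: M, variants: [m.4833A>G, m.5108T>C, m.9377A>G, m.16362T>C]}
  G2: {parent: G, variants: [m.7600G>A, m.13563A>G]}
  M7: {parent: M, variants: [m.9824T>C, m.16297T>C]}
  M7b: {parent: M7, variants: [m.4048G>A, m.5351A>G, m.6680T>C, m.12405C>T, m.15110G>A]}
  M8: {parent: M, variants: [m.4715A>G, m.7196C>A, m.8584G>A, m.15487A>T, m.16298T>C]}
  Z: {parent: M8, variants: [m.6752A>G, m.9090T>C, m.15784T>C, m.16185C>T, m.16260C>T]}
  A: {parent: N, variants: [m.235A>G, m.663A>G, m.1736A>G, m.4248T>C, m.4824A>G,
                            m.8794C>T, m.16290C>T, m.16319G>A]}
  Y: {parent: N, variants: [m.8392G>A, m.14178T>C, m.16231T>C]}
  Y1: {parent: Y, variants: [m.3834G>A, m.16126T>C]}
  B: {parent: N, variants: [m.8281_8289del, m.16189T>C]}
  B4: {parent: B, variants: [m.16217T>C]}
  F: {parent: N, variants: [m.3970C>T, m.13928G>C]}
  F1: {parent: F, variants: [m.6392T>C, m.10310G>A]}
  "F1a'c": {parent: F1, variants: [m.16172T>C]}
  F1a: {parent: "F1a'c", variants: [m.16304T>C]}
  F1a1: {parent: F1a, variants: [m.16162A>G]}
  F3: {parent: F, variants: [m.3434A>G]}
  F3a: {parent: F3, variants: [m.5913G>A, m.16355C>T]}
  F4: {parent: F, variants: [m.12630G>A, m.16093T>C]}

# Macro-haplogroup roll-up used for frequency tables; nodes not listed
# (rCRS, N-internal M) report as "other".
macro:
  D: [D, D4, D4e1a]
  G: [G, G2]
  M7: [M7, M7b]
  M8: [M8, Z]
  A: [A]
  B: [B, B4]
  N: [N, Y, Y1]
  H2: [H2]
  F: [F, F1, "F1a'c", F1a, F1a1, F3, F3a, F4]
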