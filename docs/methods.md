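# Methods

## Reference model

The MT-TT gene is modelled as the rCRS (NC_012920.1) segment
m.15888–15953 (66 nt, forward strand; the gene is H-strand encoded, so
the genomic sequence reads as the tRNA with T for U). The
mtDNA→tRNAdb position map is built from 15 curated anchor mappings by
piecewise constant-offset interpolation: every coordinate inherits the
offset of the nearest anchor at or upstream, so jumps in the canonical
numbering (positions 20–21, 53 and 57–60 are absent from this tRNA's
numbering) occur exactly at an anchor. The loader rejects anchor sets
that are non-monotone or too tight to fill strictly increasingly, and
verifies that every mapped position carries a structural-element label.
The tRNAdb numbering of mt-tRNAs is irregular around the D- and
T-arms; the anchors are authoritative and the interpolation is the
simplest map consistent with them, shipped as an editable YAML file
rather than derived from structure prediction.

Structural elements follow the cloverleaf ranges (acceptor stem 1–7 /
66–72, D-arm, anticodon arm, variable loop 44–48, T-arm, discriminator
73+), with two curated deviations kept verbatim from the annotation
this model reproduces: position 61 is labelled T-loop, and the
(53, 61) T-stem pair is omitted from the pairing table, so site 61
annotates as an unpaired loop position. The D-arm retains only its
12:23 pair. All seven shipped pairs are Watson–Crick complementary in
the reference sequence (checked in the tests).

## Synthetic data

The generator's defaults are the study conditions: 352 cases, 376
controls, and the 15 published per-variant carrier counts (41 case
carriers, 23 control carriers, one variant per carrier — consistent
with the published arithmetic). Carriers are **assigned**, not
binomially sampled: subjects are shuffled by the seed and the first
*k* receive each variant, so every per-variant count is exact by
construction and the headline numbers are seed-invariant. All variants
are implanted homoplasmically (every change in the study appeared
homoplasmic). Sequencing error, chromatograms and heteroplasmy are not
simulated; consensus sequences are exact. Consequently the calling
round-trip tests demonstrate correctness of the comparison logic, not
robustness to base-calling noise in real traces.

The 44-species alignment is generated per site: at each tRNAdb
position with a specified match count *k*, exactly *k* of the 44 rows
(human always among them) carry the human base and the rest carry a
seeded random other base; unspecified sites are fully conserved. The
shipped match counts are chosen so 100·k/44 reproduces the published
CI at each variant site. Site 42 is the one exception: the published
75.45 is not expressible as k/44 (75.00 = 33/44, 77.27 = 34/44) and is
treated as a typographical artefact; the generator uses k = 33. The
synthetic alignment reproduces column statistics only — it has no
phylogenetic covariance structure, so conservation values are exact by
construction rather than estimates.

Carrier mitogenomes are simulated as the root→node defining variants
of a haplogroup plus `N_PRIVATE_VARIANTS = 8` private substitutions at
seeded random positions (a round number in the range of per-lineage
private variation seen in East Asian mitogenome surveys). Private
variants avoid every defining-variant position tree-wide (collisions
are redrawn), which makes haplogroup recovery exact by construction —
the round-trip property validates the classifier, not the realism of
mutation placement.

## Variant calling

Consensus vs rCRS comparison is by exact global alignment (edlib,
Needleman–Wunsch with unit costs) on the 66-nt segment; the segment is
short enough that exactness costs nothing. Equal-length inputs are
diffed position-wise, which is the minimal edit script when only
substitutions and deletions are admitted. Insertions relative to rCRS
and length differences beyond 3 nt are hard errors naming the subject,
as are IUPAC ambiguity codes (heteroplasmy codes are rejected, not
interpreted). Deletions inside homopolymer runs are placement-ambiguous;
the default normalization is the 5′-most position of the run on the
forward strand, which renders the T-run deletion at 15940–15944 as
m.15940DelT, the label used in the mitochondrial literature for this
variant. A `3prime` mode is available. Every call set is re-applied
to the reference and must reproduce the subject exactly.

## Conservation and classification

CI = 100 · matches/rows, human row included, rounded half-up to two
decimals (`decimal.Decimal`, matching the published rendering). Gap
characters count as mismatching rows by default (`exclude` mode drops
them from the denominator). The conservation threshold is **inclusive**
(CI ≥ 70): the smallest CI in the conserved group is 70.45, so the
boundary case is unobservable in the study data; inclusive is the
stabler choice.

The default classification rule is: catalog membership → *known*;
else (CI ≥ 70% OR deletion) AND control carrier frequency ≤ 1% →
*putative*; else *polymorphism*. The control-frequency cap of 1% sits
in the open interval between the largest putative control frequency
(3/376 ≈ 0.80%) and the smallest control frequency that drives a
polymorphism call (13/376 ≈ 3.46%); any cap in that interval gives the
same grouping, and 1% is the conventional rare-variant cut. Deletions
pass the conservation arm unconditionally because a base deletion
removes its structural position outright — conservation of the deleted
base is not informative about the structural consequence. A stricter
preset (`RuleConfig.strict_absence`: CI must exceed the cut, controls
must be strictly zero, deletions get no pass) matches the narrative
phrasing of such screens but does not reproduce the published grouping,
which lists control carriers for five putative variants; both rule sets
are exposed and every classification carries a fired-rule trace.

## Statistics

The carrier comparison is the uncorrected Pearson χ² on the 2×2 table
(carriers vs non-carriers by arm); on (41, 311; 23, 353) this gives
χ² = 6.9355, p = .0085. Yates' continuity correction (p ≈ .0123) is
exposed as a flag, off by default, because the published p-value is
the uncorrected one. The p-value is the upper tail of χ²(1) via
scipy's survival function (regularized incomplete gamma); the test
suite cross-checks it against the closed form erfc(√(x/2)), exact for
1 df, to 6 significant digits over a grid of tables. Fisher's exact
test is available as an alternative, not used for any headline number.
Percentages are rendered half-up to two decimals (frequencies) or one
decimal (haplogroup tables).

## Haplogroups

Assignment scores every node as matched − missing over the root→node
defining variants; the winner maximizes the score with ties broken by
fewer missing, then greater depth, then name. Fewer-missing before
depth means a profile carrying a clade's full shallow motif but only
part of a deeper branch motif is called at the shallow node — the
conservative reading of partial support. Back-mutations and recurrent
variants are not modelled: a defining variant is simply present or
absent. The empty profile maps to the root (rCRS).

The shipped tree is a ~27-node curated miniature covering the
haplogroups observed among the study's carriers (D/D4/D4e1a, G/G2,
M7/M7b, M8/Z, A, Y/Y1, B/B4, F-subclades, H2, N, M), with
PhyloTree-style defining motifs expressed relative to rCRS: the
ubiquitous non-H2 basal substitutions hang on N and the macrohaplogroup
M motif nests under it. It is a declared, replaceable input, not a
PhyloTree import; control-population haplogroup frequencies (which
would need the real control genomes) are out of scope. The carrier→
haplogroup table ships as data (subgroups: the 20 putative-variant
carriers, 4 m.15951A>G carriers, 8 m.15927G>A carriers = 32 sequenced
mitogenomes); the m.15927 subgroup composition (5 B, 2 G, 1 F) follows
the published 62.5/25.0/12.5 split.

## Problem sizes and determinism

The default study runs the full cohort (728 subjects), the 44-species
alignment and 32 simulated mitogenomes; the whole pipeline completes in
about a second, and the test suite (including the tree-wide haplogroup
round trip: 26 nodes × {0, 5, 10} private × 20 seeds) in a few seconds.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration yields
byte-identical output bundles.

## Known limitations

- Consensus inputs must span exactly the gene segment; flanking
  sequence trimming is not implemented.
- Insertions relative to rCRS are rejected rather than called.
- The conservation alignment and haplogroup tree are synthetic/curated
  stand-ins shaped to the published summary statistics; they support
  method validation, not new biological inference.
- Heteroplasmy fractions, chromatogram-level evidence and
  pathogenicity point-scoring schemes (Yarham/MitoTIP style) are out
  of scope.
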