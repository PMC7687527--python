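# Structural model of the human mitochondrial tRNA-Thr gene (MT-TT).
#
# Coordinates are 1-based inclusive rCRS (NC_012920.1) positions on the
# forward strand; tRNA structural positions use the canonical tRNAdb
# 1-76 numbering.  The mtDNA->tRNAdb map is defined by a set of anchor
# positions and filled in by piecewise constant-offset interpolation:
# every coordinate between two anchors inherits the offset of the
# upstream anchor, so jumps in the numbering (skipped canonical
# positions) happen exactly at an anchor.
gene: MT-TT
product: tRNA-Thr
strand: H

reference:
  fasta: rcrs_mt_tt.fasta
  start: 15888
  end: 15953

numbering:
  # mtDNA coordinate -> tRNAdb position
  anchors:
    15900: 13
    15901: 14
    15907: 22
    15908: 23
    15924: 39
    15927: 42
    15928: 43
    15930: 45
    15931: 46
    15938: 54
    15940: 56
    15941: 61
    15943: 63
    15949: 69
    15951: 71

# Structural element per tRNAdb position (inclusive ranges).  Position 61
# is labelled T-loop (rather than T-stem) and the 12:23 pair is the only
# D-arm pair retained; both choices follow the curated annotation of this
# tRNA rather than the generic cloverleaf template.
elements:
  acceptor stem: [[1, 7], [66, 72]]
  DHU stem: [[8, 12], [23, 26]]
  DHU loop: [[13, 22]]
  anticodon stem: [[27, 31], [39, 43]]
  anticodon loop: [[32, 38]]
  variable loop: [[44, 48]]
  T-stem: [[49, 53], [62, 65]]
  T-loop: [[54, 61]]
  discriminator: [[73, 76]]

# Watson-Crick stem pairs (unordered tRNAdb position pairs).
pairing:
  - [2, 71]
  - [3, 69]
  - [12, 23]
  - [27, 43]
  - [28, 42]
  - [31, 39]
  - [51, 63]
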