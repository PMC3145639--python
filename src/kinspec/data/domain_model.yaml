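# Anchored model of the protein-kinase catalytic domain.
#
# Domain detection looks for the canonical conserved motifs of the kinase
# fold, in order, with bounded spacing between consecutive anchors. The
# specificity-determining-residue (SDR) positions are defined relative to
# these anchors. The anchor set, the kinase-type patterns and the SDR offset
# table below are illustrative defaults following the anchor-relative scheme
# of the method; the published position list from the structural analysis of
# kinase-peptide complexes is not reproduced here. Swap this file (or pass a
# custom model) to use a different coordinate frame, or plug in an external
# profile-HMM aligner via kinase_domain.detect_catalytic_domain's seam.
version: kinspec-domain-model-1
anchors:
  # name, regex pattern, min/max gap (residues between the previous anchor's
  # end and this anchor's start; the first anchor may sit anywhere).
  - name: gly_loop        # glycine-rich phosphate-binding loop, GxGxxG
    pattern: "G.G..G"
    min_gap: 0
    max_gap: 0
  - name: vaik            # beta-3 lysine motif ([VAI]xK)
    pattern: "[VAI].K"
    min_gap: 8
    max_gap: 60
  - name: hrd             # catalytic loop HRD
    pattern: "HRD"
    min_gap: 40
    max_gap: 160
  - name: dfg             # activation-segment DFG
    pattern: "DFG"
    min_gap: 8
    max_gap: 40
  - name: ape             # activation-segment APE
    pattern: "APE"
    min_gap: 12
    max_gap: 60
# Kinase-type patterns, matched against the detected domain in order; first
# match wins, and serine/threonine is the logged default when none match.
# The patterns read the catalytic-loop octamer starting at the HRD anchor.
type_patterns:
  - kinase_type: CMGC
    pattern: "HRDLKPQN"
  - kinase_type: tyrosine
    pattern: "HRD[LIV]A[AT]RN"
  - kinase_type: serine/threonine
    pattern: "HRD[LIV]K..N"
# SDR positions as (anchor, signed offset from the anchor's first residue).
# Offsets deliberately avoid the literal anchor spans and the catalytic-loop
# octamer so planted fixtures cannot collide with the motifs themselves.
sdr_positions:
  - {anchor: hrd, offset: -2}
  - {anchor: hrd, offset: -1}
  - {anchor: dfg, offset: 3}
  - {anchor: dfg, offset: 4}
  - {anchor: ape, offset: -2}
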