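# Consensus-element definitions for upstream-region scanning.
#
# Patterns are IUPAC degenerate strings.  The two E-box entries are the
# standard generic/canonical forms; the remaining strings are editable
# literature defaults and should be reviewed against the consensus
# definitions used in your own study before interpretation.
motifs:
  E_box_generic: CANNTG
  E_box_canonical: CACGTG
  W_box: TTGACY
  CRE: TGACGTCA
  PERR: CACGCTTA
  TER: CACGTT
  PDP1: TTATGTAA
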