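# Experimentally observed codon-reading options per wobble base.
#
# Keys are the (unmodified parent) base at the anticodon wobble position;
# values are the alternative sets of codon third bases that a tRNA with that
# wobble base has been observed to read.  C is restricted to cognate binding
# (C:G) and G constitutively reads the pyrimidines (G:{C,U}); A (usually via
# inosine or other modification) and U (via its many modifications) admit
# several alternatives.  Override with a file of the same shape to change
# what counts as a plausible reading.
A:
  - [U]
  - [U, C]
  - [U, C, A]
U:
  - [A]
  - [A, G]
  - [A, G, U]
  - [A, C, G]
  - [A, C, G, U]
C:
  - [G]
G:
  - [C, U]
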