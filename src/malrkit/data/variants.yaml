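# Named structural variants of the THE1A lineage, 1-based coordinates on
# the THE1B LTR consensus frame (227_242del is on the MSTB1_TS/MSTB1 frame).
# insert_seq is used when planting an insertion variant into a consensus;
# genotyping of insertions checks presence of inserted bases, not content.
reference: THE1B
variants:
  - name: 186ins
    kind: insertion
    start: 186
    insert_seq: C
  - name: 204del
    kind: deletion
    start: 204
    end: 204
    note: single-base deletion within the putative ZNF100-bound locus, downstream of the TSS
  - name: 226_235del
    kind: deletion
    start: 226
    end: 235
  - name: 303_312delinsTT
    kind: delins
    start: 303
    end: 312
    replacement: TT
  - name: 227_242del
    kind: deletion
    start: 227
    end: 242
    reference: MSTB1_TS
    note: 16 bp deletion distinguishing the Tarsiiformes-specific family from MSTB1/MSTB
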