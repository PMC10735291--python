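# U3/R/U5 segment boundaries (1-based, contiguous) for the synthetic
# THE1B-like LTR consensus shipped with the simulator (length 360).
# The TSS sits at the U3|R junction (u3_end + 1 = 191), so position 204 is
# downstream of the TSS and travels with the 5' LTR during replication.
# Boundaries are explicit configuration: supply your own file for a real
# consensus model.
length: 360
u3_end: 190
r_end: 260
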