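# Default engineered-genome scenario: three host contigs; the construct is
# integrated into the first one as an intact copy plus a truncated copy
# lacking the GS and HC cassettes, two extra LC copies (one inverted), a 240
# bp fragment borrowed from the second contig in front of the insert, and a
# 4-fold amplified region immediately upstream of the insertion point.  The
# third contig carries a genomic homolog of the GS marker cassette.
host_lengths: [40000, 12000, 10000]
construct_length: 8000
hc: [600, 2400]
lc: [2600, 4000]
gs: [4200, 5600]
promoter: [400, 600]
truncated_copy: [2400, 4200]
extra_copy: [2400, 4200]
insertion_position: 20000
amplified_region: [16000, 20000]
amplification_factor: 4
fragment_source: [6000, 6240]
gs_homolog_position: 4000
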