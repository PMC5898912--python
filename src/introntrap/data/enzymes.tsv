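# Type IIS enzyme cut geometry (standard biochemistry; editable).
# recognition is the top-strand motif; cut offsets are measured in nt
# downstream of the recognition-site 3' end on the top (cut_offset_top)
# and bottom (cut_offset_bottom) strands; all three leave 4-nt 5' overhangs.
# name	recognition	cut_offset_top	cut_offset_bottom
BsaI	GGTCTC	1	5
BbsI	GAAGAC	2	6
BsmBI	CGTCTC	1	5
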