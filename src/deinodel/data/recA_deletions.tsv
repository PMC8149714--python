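# Published chromosome II deletions of five D. radiodurans recA isolates.
# Coordinates are 1-based, anchored at the beginning of the breakpoint
# repeat, in two coordinate systems: the study's own reference wild type
# (start/end) and the 1999 wild-type assembly (wt1999_start/wt1999_end).
# printed_length is the deletion length as published, which for four
# isolates differs slightly from end - start (see deinodel.published).
isolate	element	start	end	printed_length	repeat	wt1999_start	wt1999_end
S1	chrII	162314	226262	63948	CGAGTTCGCGC	162302	226250
S2	chrII	175704	227142	51423	CAGCC	175692	227130
R1	chrII	162602	240541	77912	CGCCC	162590	240528
R2	chrII	160014	247789	87759	CGATGG	160002	247776
R6	chrII	187421	222947	35522	GGCA	187407	222934
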