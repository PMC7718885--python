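subject	group	score
ccRCC 2	ccRCC	-27.24
ccRCC 3	ccRCC	-28.34
ccRCC 4	ccRCC	-29.61
ccRCC 5	ccRCC	-16.22
ccRCC 6	ccRCC	-12.31
ccRCC 7	ccRCC	-23.05
ccRCC 8	ccRCC	-9.44
ccRCC 9	ccRCC	-13.78
ccRCC 10	ccRCC	-16.52
ccRCC 11	ccRCC	-27.06
ccRCC 12	ccRCC	-21.53
ccRCC 13	ccRCC	-7.11
ccRCC 17	ccRCC	-12.76
HS 1	HS	2.55
HS 2	HS	-7.98
HS 3	HS	-1.54
HS 4	HS	-5.66
HS 5	HS	-0.17
HS 6	HS	6.28
HS 7	HS	-5.71
HS 8	HS	1.26
HS 9	HS	-5.93
HS 10	HS	-2.19
HS 11	HS	31.68
HS 12	HS	-17.56
HS 13	HS	4.23
HS 14	HS	-6.31
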