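feature	level	count
cohort	tumour	497
cohort	normal	52
gleason	6	50
gleason	7	287
gleason	8	67
gleason	9	140
gleason	10	4
stage	T2a	14
stage	T2b	10
stage	T2c	192
stage	T3a	173
stage	T3b	140
stage	T4	12
grade_group	1	50
grade_group	2	171
grade_group	3	123
grade_group	4	93
grade_group	5	111
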