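model	response	term	value
whole_blood	status	b0	0.5823
whole_blood	status	b1	0.0004
whole_blood	status	b2	0.0829
whole_blood	status	b3	-0.0011
whole_blood	status	d1	-0.0547
whole_blood	status	d2	0.0569
whole_blood	status	d3	-0.0022
whole_blood	status	d4	0.0123
whole_blood	status	d5	-0.0044
whole_blood	status	d6	-0.0080
whole_blood	sequence	b0	0.9597
whole_blood	sequence	b1	-0.0008
whole_blood	sequence	b2	-0.0698
whole_blood	sequence	b3	0
whole_blood	sequence	d1	-0.0231
whole_blood	sequence	d2	0.0025
whole_blood	sequence	d3	0.0206
whole_blood	sequence	d4	0.0474
whole_blood	sequence	d5	-0.0260
whole_blood	sequence	d6	-0.0214
celltype	status	b0	0.5712
celltype	status	b1	0.0006
celltype	status	b2	0.0961
celltype	status	b3	-0.0014
celltype	status	b4	0
celltype	status	d1	-0.0528
celltype	status	d2	0.0520
celltype	status	d3	-0.0052
celltype	status	d4	0.0286
celltype	status	d5	-0.0061
celltype	status	d6	-0.0212
celltype	status	c1	-0.0002
celltype	status	c2	0.0311
celltype	status	c3	0.0094
celltype	status	c4	-0.0472
celltype	status	c5	0.0036
celltype	status	c6	0.0344
celltype	sequence	b0	0.9468
celltype	sequence	b1	0.0002
celltype	sequence	b2	-0.0132
celltype	sequence	b3	-0.0003
celltype	sequence	b4	-0.0037
celltype	sequence	d1	-0.0011
celltype	sequence	d2	0.0035
celltype	sequence	d3	0.0048
celltype	sequence	d4	0.0083
celltype	sequence	d5	-0.0131
celltype	sequence	d6	-0.0009
celltype	sequence	c1	0.0521
celltype	sequence	c2	0.0331
celltype	sequence	c3	0.0611
celltype	sequence	c4	0.0402
celltype	sequence	c5	-0.0549
celltype	sequence	c6	-0.1032
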