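chr	pos_bp	cM_female	cM_male
1	1000000	0.0	0.0
1	2000000	2.5	1.5
1	3000000	5.0	3.0
1	6000000	12.0	7.0
2	1000000	0.0	0.0
2	4000000	8.0	4.0
2	9000000	20.0	10.0
3	2000000	0.0	0.0
3	5000000	30.0	12.0
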