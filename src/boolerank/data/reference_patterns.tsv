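gene_symbol	gene_id	up	down	pattern	printed_rank
KLK6	5653	1	0	1011001	0.697808
IRAK1	3654	1	0	0111010	0.607561
CDC7	8317	1	0	0111010	0.607561
CHEK1	1111	1	0	0111010	0.607561
BUB1	699	1	0	0111010	0.607561
CHEK2	11200	1	0	0111010	0.607561
STC2	8614	1	0	1011010	0.584684
DAB2	1601	0	1	0011011	0.743532
VIM	7431	0	1	0011011	0.743532
FOXL2	668	0	1	0011101	0.735481
LCN2	3934	0	1	1011001	0.697808
PGR	5241	0	1	0011110	0.644578
AR	367	0	1	0011110	0.644578
IGF1R	3480	0	1	0111010	0.607561
LYN	4067	0	1	0111010	0.607561
IGFBP7	3490	0	1	1011010	0.584684
CLU	1191	0	1	1011010	0.584684
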