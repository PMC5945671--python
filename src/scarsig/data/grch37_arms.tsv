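chrom	length	p_end	q_start
1	249250621	121535434	124535435
2	243199373	92326171	95326172
3	198022430	90504854	93504855
4	191154276	49660117	52660118
5	180915260	46405641	49405642
6	171115067	58830166	61830167
7	159138663	58054331	61054332
8	146364022	43838887	46838888
9	141213431	47367679	50367680
10	135534747	39254935	42254936
11	135006516	51644205	54644206
12	133851895	34856694	37856695
13	115169878	16000000	19000001
14	107349540	16000000	19000001
15	102531392	17000000	20000001
16	90354753	35335801	38335802
17	81195210	22263006	25263007
18	78077248	15460898	18460899
19	59128983	24681782	27681783
20	63025520	26369569	29369570
21	48129895	11288129	14288130
22	51304566	13000000	16000001
X	155270560	58632012	61632013
Y	59373566	10104553	13104554
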