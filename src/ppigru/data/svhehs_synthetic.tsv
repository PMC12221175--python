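residue	c1	c2	c3	c4	c5	c6	c7	c8	c9	c10	c11	c12	c13
A	15.6421	144.0399	42.4389	64.4244	11.8398	-0.7400	92.0828	36.6379	103.6428	120.6320	74.4598	114.4630	6.4997
C	69.9675	15.8744	75.2191	59.7818	35.7224	43.3562	102.3941	41.9532	110.5742	109.7895	86.5667	94.8028	-63.2788
D	10.8376	115.5147	93.1928	61.7834	-18.6412	15.4632	94.1712	44.9809	105.0181	64.0119	91.6210	106.6060	16.2233
E	12.7701	89.6575	72.3566	61.5947	-2.4361	53.2271	98.1821	42.9152	106.6107	131.3649	65.3429	74.0763	-49.4649
F	36.6824	134.9086	74.2180	61.0398	-0.9143	31.5049	94.6590	34.3280	104.1912	73.2994	99.9159	95.7503	17.5510
G	26.4470	66.2995	84.6449	69.4236	43.3276	21.7239	93.9824	48.6623	103.9084	155.8586	100.7024	127.5038	39.6360
H	-1.9547	96.4604	86.3444	59.3925	56.0318	24.8014	99.6638	51.6197	110.3758	99.9770	104.9643	75.6399	20.0085
I	-37.1881	85.6524	79.9266	70.9117	15.4907	24.3647	86.6467	40.2111	108.7451	107.6262	80.1437	94.7624	71.6265
K	5.9463	132.5781	96.9780	71.8476	-52.2311	25.2860	96.2042	50.3284	106.0424	75.1080	115.8610	137.1091	22.8717
L	-0.0243	102.0209	80.3293	65.4566	38.4787	61.4217	98.9835	38.7571	104.3131	20.8512	93.6954	56.8336	36.1991
M	21.6873	108.5567	92.0762	67.0474	25.0148	64.1700	98.4105	37.7496	105.0939	110.1707	82.1843	83.3530	7.9857
N	3.1560	106.4638	51.6576	70.9936	7.8423	62.3053	95.3366	36.9654	104.8468	109.7556	101.5957	82.5736	2.6677
P	22.1953	112.0583	68.4386	65.0967	4.6609	67.2477	93.4000	52.0139	105.6928	51.6259	94.7020	22.2180	23.3085
Q	0.9566	126.8264	94.3510	66.6989	2.9076	11.8111	101.9678	41.1938	104.6347	107.7171	76.1260	38.0542	58.8019
R	53.6762	49.8485	65.3463	71.6270	-2.9477	-9.6490	91.5218	38.7769	103.8901	120.0832	95.2727	47.7040	-3.9407
S	9.3833	167.9584	72.7116	65.6844	1.5501	21.1822	86.8396	38.2321	107.8571	123.6259	81.0043	105.1551	33.3891
T	26.2828	143.3004	73.5595	60.3933	-1.8820	23.8421	95.3012	37.5730	104.7577	60.7482	73.4498	91.7138	55.9567
V	7.2782	130.8187	91.1815	52.4971	29.6155	-3.5771	92.3605	50.5931	106.8084	97.8093	54.1146	-16.4325	-8.3972
W	39.1665	130.4838	73.7578	62.3051	8.1052	19.6490	89.5714	37.9484	108.4802	88.7961	83.5748	33.4799	39.4174
Y	4.9694	88.0065	82.3951	64.5592	-10.8504	48.1580	89.2440	45.5578	104.8554	76.8631	79.1370	96.9976	16.3427
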