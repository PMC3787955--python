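CNVR NO.	Chr	Start	End	Length (Kb)	Status	Breed
1	1	27137	4021371	3994.234	Gain-Loss	Minzhu pig
4	1	14913515	16205785	1292.27	Gain-Loss	Minzhu pig
6	1	38187823	39892124	1704.301	Gain-Loss	Minzhu pig
8	1	59146777	60116291	969.514	Gain-Loss	Minzhu pig
9	1	78080106	78512135	432.029	Loss	Large-White
13	1	97861336	102022988	4161.652	Gain-Loss	Large-White
14	1	123741378	125430919	1689.541	Gain-Loss	Minzhu pig
23	1	202360098	202460519	100.421	Gain	Minzhu pig
28	1	233648692	235129449	1480.757	Gain-Loss	Minzhu pig
30	1	290536560	295554054	5017.494	Gain-Loss	Minzhu pig
31	2	42783	6186192	6143.409	Gain-Loss	Minzhu pig
32	2	9612578	14884403	5271.825	Gain-Loss	Minzhu pig
39	2	55639944	57533047	1893.103	Gain-Loss	Minzhu pig
51	4	29558904	29848274	289.37	Gain	Minzhu pig
53	4	40547805	53260169	12712.364	Gain-Loss	Minzhu pig
55	4	80557625	80683923	126.298	Loss	Minzhu pig
62	5	33971	2576759	2542.788	Gain-Loss	Minzhu pig
64	5	14977039	23972011	8994.972	Gain-Loss	Minzhu pig
67	5	29271805	32046817	2775.012	Gain-Loss	Minzhu pig
71	5	64939963	73159278	8219.315	Gain-Loss	Minzhu pig
72	6	26646	2373898	2347.252	Gain-Loss	Minzhu pig
83	6	34507867	35720036	1212.169	Gain	Minzhu pig
84	6	36433467	37058702	625.235	Gain	Minzhu pig
89	7	29484113	29946052	461.939	Gain-Loss	Minzhu pig
93	7	54923282	59344416	4421.134	Loss	Minzhu pig
97	7	71399968	85475026	14075.058	Gain-Loss	Minzhu pig
99	7	95002189	95880768	878.579	Gain	Minzhu pig
104	7	122242402	123874154	1631.752	Gain-Loss	Minzhu pig
107	8	7879866	8054169	174.303	Gain-Loss	Minzhu pig
110	8	27976730	29061313	1084.583	Gain-Loss	Minzhu pig
111	8	46183156	47937663	1754.507	Gain-Loss	Minzhu pig
112	8	52363564	53392239	1028.675	Gain	Minzhu pig
118	9	27950	3729624	3701.674	Gain-Loss	Minzhu pig
120	9	5559852	6597228	1037.376	Gain-Loss	Minzhu pig
122	9	44705850	45388279	682.429	Gain-Loss	Minzhu pig
125	9	82946155	92571240	9625.085	Gain-Loss	Minzhu pig
137	11	22392667	36576409	14183.742	Gain-Loss	Minzhu pig
148	12	8839980	20037607	11197.627	Gain-Loss	Minzhu pig
149	12	19662620	37002457	17339.837	Gain-Loss	Minzhu pig
160	13	92117925	119407655	27289.73	Gain-Loss	Minzhu pig
169	14	45833	7887586	7841.753	Gain-Loss	Minzhu pig
175	14	13242399	21656861	8414.462	Gain-Loss	Minzhu pig
176	14	28551814	36527320	7975.506	Gain-Loss	Minzhu pig
178	14	46604684	56259408	9654.724	Gain-Loss	Minzhu pig
185	14	67634813	77654554	10019.741	Gain-Loss	Minzhu pig
192	14	110998360	113178611	2180.251	Gain-Loss	Minzhu pig
197	14	137251412	148678088	11426.676	Gain-Loss	Minzhu pig
209	15	25744213	27098633	1354.42	Gain	Minzhu pig
211	15	40187988	43203855	3015.867	Gain-Loss	Minzhu pig
223	16	823535	1293412	469.877	Gain-Loss	Minzhu pig
225	16	3590605	4172931	582.326	Gain-Loss	Minzhu pig
230	16	45805292	50607024	4801.732	Loss	Minzhu pig
231	16	72854046	74717034	1862.988	Gain	Minzhu pig
232	17	1347911	2345614	997.703	Gain-Loss	Minzhu pig
233	17	3231266	3510331	279.065	Gain	Minzhu pig
235	17	11096541	11214207	117.666	Gain	Minzhu pig
246	X	5054064	18192210	13138.146	Gain	Minzhu pig
247	X	6734423	24477135	17742.712	Gain-Loss	Minzhu pig
248	X	65177195	71802709	6625.514	Gain-Loss	Minzhu pig
249	X	106109244	117864445	11755.201	Gain	Minzhu pig
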