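dataset	size	m	tau	RP-CNN	ResNet	FCN	RP-FCN	HIVE-COTE	FCN-RCF	ALSTM-FCN	MS-RP-ResNet	MS-RP-FCN
Adiac	64	2	1	0.2800	0.1740	0.1430	0.1709	0.1846	0.1550	0.1330	0.1560	0.1379
Beef	64	2	1	0.0800	0.2330	0.2500	0.1667	0.2773	0.0300	0.0667	0.0667	0.1333
CBF	64	2	1	0.0050	0.0060	0	0.0033	0.0006	0	0	0	0
ChlorineCon	112	2	1	0.1049	0.1720	0.1570	0.1992	0.2749	0.0680	0.1930	0.1987	0.1992
CinTorso	128	3	4	0.0087	0.2290	0.1870	0.2866	0.0120	0.0140	0.0942	0.0486	0.1123
Coffee	64	2	1	0	0	0	0	0.0018	0	0	0	0
CricketX	64	3	4	0.2718	0.1790	0.1850	0.2187	0.1696	0.2160	0.1949	0.1538	0.1821
CricketY	64	3	4	0.2462	0.1950	0.2080	0.2349	0.1630	0.1720	0.1795	0.1564	0.1718
CricketZ	64	3	4	0.2667	0.1870	0.1870	0.2064	0.1523	0.1620	0.1692	0.1487	0.1615
DiatomSizeR	64	2	1	0.0098	0.0690	0.0700	0.0196	0.0581	0.0230	0.0261	0.0065	0.0098
ECG200	64	2	1	0	0.1300	0.1000	0.0800	0.1181	0.0625	0.0900	0.0500	0.0800
ECGFiveDays	64	3	4	0.0023	0.0450	0.0150	0	0.0105	0.0100	0.0046	0	0
FaceAll	96	2	1	0.1900	0.1660	0.0710	0.1775	0.0037	0.0980	0.0343	0.0627	0.0320
FaceFour	96	2	1	0	0.0680	0.0680	0.0341	0.0505	0.0500	0.0568	0.0795	0.0400
FacesUCR	64	2	1	0.0483	0.0420	0.0520	0.0751	0.0164	0.0870	0.0566	0.0585	0.0561
FiftyWords	48	3	4	0.2600	0.2730	0.3210	0.1846	0.1932	0.2880	0.1758	0.1692	0.1780
Fish	64	2	1	0.0850	0.0110	0.0290	0	0.0238	0.0210	0.0229	0.0114	0
GunPoint	64	2	1	0	0.0070	0	0	0.0033	0	0	0	0
Haptics	64	2	1	0.5390	0.4940	0.4490	0.4578	0.4697	0.4610	0.4351	0.4708	0.4675
InlineSkate	128	2	1	0.6436	0.6350	0.5890	0.5382	0.4741	0.5660	0.5073	0.5655	0.5491
ItaPowDemand	16	2	1	0.0330	0.0400	0.0300	0.0447	0.0322	0.0310	0.0398	0.0262	0.0292
Lightning2	64	3	4	0.1639	0.2460	0.1970	0.0984	0.2030	0.1450	0.2131	0.1148	0.0984
Lightning7	64	3	4	0.2600	0.1640	0.1370	0.1470	0.1889	0.0910	0.1781	0.1440	0.1233
Mallat	128	3	4	0.0512	0.0210	0.0200	0.0752	0.0245	0.0440	0.0162	0.0473	0.0422
MedicalImg	96	2	1	0.2658	0.2280	0.2080	0.2329	0.1846	0.1640	0.2039	0.2066	0.1947
MoteStrain	80	2	1	0.1182	0.1050	0.0500	0.1741	0.0532	0.0760	0.0639	0.0847	0.0831
NonInThorax1	128	3	4	0.0580	0.0520	0.0390	0.0580	0.0683	0.0260	0.0249	0.0575	0.0361
NonInThorax2	128	3	4	0.0489	0.0490	0.0450	0.0579	0.0477	0.0280	0.0336	0.0453	0.0366
OliveOil	96	2	1	0.1100	0.1330	0.1670	0.1333	0.1023	0	0.0667	0.0667	0.0500
OSULeaf	96	2	1	0.2900	0.0210	0.0120	0.0909	0.0295	0.0180	0.0041	0.0248	0.0165
SonyAIRobot1	64	2	1	0.0499	0.0150	0.0320	0.0266	0.1132	0.0420	0.0300	0.0166	0.0067
SonyAIRobot2	64	2	1	0.0923	0.0380	0.0380	0.0546	0.0546	0.0640	0.0252	0.0535	0.0210
StarLigCurves	128	3	4	0.0234	0.0250	0.0330	0.0238	0.0185	0.0180	0.0233	0.0195	0.0180
SwedishLeaf	64	2	1	0.0600	0.0420	0.0340	0.0304	0.0314	0.0570	0.0144	0.0272	0.0272
Symbols	64	3	4	0.0824	0.1280	0.0380	0.0181	0.0342	0.0400	0.0131	0.0141	0.0161
SynControl	64	2	1	0.3433	0	0.0100	0.3100	0.0004	0.0382	0.0100	0	0
Trace	64	2	1	0	0	0	0	0	0.0940	0	0	0
TwoLeadECG	64	2	1	0.0026	0	0	0.0018	0.0065	0.0643	0.0009	0	0
TwoPatterns	64	2	1	0.4935	0	0.1030	0.4888	0.0001	0	0.0032	0	0
UWaveX	64	3	4	0.3582	0.2130	0.2460	0.3778	0.1616	0.2180	0.1519	0.1790	0.1963
UWaveY	64	3	4	0.3439	0.3320	0.2750	0.3425	0.2245	0.2320	0.2342	0.2496	0.2725
UWaveZ	64	2	1	0.3317	0.2450	0.2710	0.3490	0.2217	0.2650	0.2018	0.2272	0.2462
Wafer	64	2	1	0	0.0030	0.0030	0.0015	0.0003	0	0.0019	0.0006	0.0011
WoSynonyms	64	2	1	0.3135	0.3680	0.4200	0.2900	0.2520	0.3380	0.3323	0.2774	0.2978
Yoga	64	2	1	0.1180	0.1420	0.1550	0.0953	0.0830	0.1120	0.0810	0.0887	0.0930
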