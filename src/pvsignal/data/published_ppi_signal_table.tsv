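pt	a	ror	ci_low	ci_high	p	nonsignal_footnote
Acute hepatic failure	103	3.262	2.683	3.966	<0.001	0
Alanine aminotransferase abnormal	3	0.682	0.219	2.119	0.808	1
Ammonia increased	3	0.213	0.069	0.661	0.001	1
Alanine aminotransferase increased	249	2.052	1.810	2.325	<0.001	0
Aspartate aminotransferase increased	171	1.687	1.450	1.962	<0.001	0
Bilirubin conjugated increased	18	3.579	2.243	5.712	<0.001	0
Blood bilirubin increased	110	1.783	1.477	2.152	<0.001	0
Cholestasis	491	12.939	11.795	14.193	<0.001	0
Coma hepatic	5	2.826	1.166	6.845	0.035	0
Hepatic encephalopathy	66	2.669	2.092	3.405	<0.001	0
Hepatic enzyme abnormal	13	1.036	0.600	1.787	0.887	1
Hepatic enzyme increased	237	1.867	1.642	2.123	<0.001	0
Hepatic failure	130	1.854	1.559	2.205	<0.001	0
Hepatic function abnormal	187	2.416	2.090	2.792	<0.001	0
Hepatic necrosis	33	4.957	3.504	7.012	<0.001	0
Hepatitis	236	4.585	4.027	5.220	<0.001	0
Hepatitis acute	96	6.823	5.560	8.373	<0.001	0
Hepatitis cholestatic	154	13.777	11.679	16.252	<0.001	0
Hepatitis fulminant	50	8.315	6.254	11.055	<0.001	0
Hepatitis toxic	16	2.775	1.693	4.551	<0.001	0
Hepatotoxicity	100	2.233	1.833	2.721	<0.001	0
Hyperammonaemia	22	1.828	1.201	2.784	0.009	0
Hyperbilirubinemia	42	1.699	1.253	2.303	0.001	0
Jaundice	218	3.283	2.870	3.755	<0.001	0
Jaundice cholestatic	31	3.926	2.748	5.608	<0.001	0
Liver function test abnormal	160	2.251	1.926	2.632	<0.001	0
Liver injury	122	3.337	2.788	3.993	<0.001	0
Liver transplant	3	0.332	0.107	1.032	0.043	1
Subacute hepatic failure	3	7.301	2.292	23.259	0.009	0
Transaminases abnormal	3	1.748	0.560	5.455	0.249	1
Transaminases increased	170	3.074	2.640	3.578	<0.001	0
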