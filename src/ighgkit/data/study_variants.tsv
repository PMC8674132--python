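snp_id	rsid	gene	exon	exon_pos	ref	alt	present_study	present_ph3	present_30x	freq_ea	freq_aa	freq_sa	freq_afr	freq_eur	freq_eas
G1_CH1_68		IGHG1	CH1	68	C	G	1	1	1		0.0050				
G1_CH1_290	rs1071803	IGHG1	CH1	290	A	G	1	1	1	0.7110	0.1803	0.0149			
G1_CH2_146		IGHG1	CH2	146	T	A	1	1	1	0.0000	0.0112	0.0000			
G1_CH2_178		IGHG1	CH2	178	C	T	1	1	1	0.0000	0.0112	0.0000			
G1_CH3_47	rs1045853	IGHG1	CH3	47	T	G	1	1	1	0.7000	0.1691	0.0149			
G1_CH3_51	rs11621259	IGHG1	CH3	51	C	A	1	1	1	0.7000	0.1691	0.0149			
G1_CH3_243		IGHG1	CH3	243	G	A	1	1	1	0.0000	0.0112	0.0000			
G1_CH3_271		IGHG1	CH3	271	C	G	1	1	1	0.1260	0.0215	0.0000			
G1_CH1_9		IGHG1	CH1	9	A	G	1	0	1			0.0160			
G1_CH1_54		IGHG1	CH1	54	G	A	1	1	0	0.0210					
G1_CH1_99		IGHG1	CH1	99	C	T	1	1	1		0.0270				
G1_CH1_144		IGHG1	CH1	144	C	T	1	1	1			0.0320			
G1_CH1_189		IGHG1	CH1	189	G	A	1	0	1	0.0050					
G1_CH1_234		IGHG1	CH1	234	T	C	1	1	1		0.0110				
G1_CH1_279		IGHG1	CH1	279	T	C	1	1	1			0.0160			
G1_H_17		IGHG1	H	17	G	A	1	1	1	0.0210					
G1_CH2_26		IGHG1	CH2	26	C	T	1	0	1		0.0270				
G1_CH2_71		IGHG1	CH2	71	G	A	1	1	1			0.0320			
G1_CH2_116		IGHG1	CH2	116	G	A	1	1	1	0.0050					
G1_CH2_161		IGHG1	CH2	161	C	T	1	1	1		0.0110				
G1_CH2_206		IGHG1	CH2	206	C	T	1	0	0			0.0160			
G1_CH3_29		IGHG1	CH3	29	A	G	1	1	1	0.0326	0.1552	0.1970			
G1_CH3_89		IGHG1	CH3	89	T	C	1	1	1	0.0163	0.0776	0.0985			
G1_CH3_179		IGHG1	CH3	179	C	T	1	1	1			0.0320			
G1_CH3_311		IGHG1	CH3	311	A	G	1	0	1	0.2900	0.2100	0.1600	0.1800	0.2400	0.2000
G2_CH1_214		IGHG2	CH1	214	A	C	1	1	1	0.5760	0.8763	0.9846			
G2_CH1_224		IGHG2	CH1	224	A	G	1	1	1	0.0000	0.0111	0.0000			
G2_CH1_226		IGHG2	CH1	226	T	C	1	1	1	0.0000	0.0111	0.0000			
G2_CH1_286		IGHG2	CH1	286	A	G	1	1	1	0.0000	0.0000	0.0442			
G2_CH2_150		IGHG2	CH2	150	A	G	1	1	1	0.5760	0.8763	0.9846			
G2_CH2_231		IGHG2	CH2	231	G	A,C	1	1	1	0.0110	0.0000	0.0903			
G2_CH3_111		IGHG2	CH3	111	G	T	1	1	1	0.0000	0.2462	0.3963			
G2_CH3_155		IGHG2	CH3	155	G	T	1	1	1	0.0000	0.0000	0.0123			
G2_CH3_213		IGHG2	CH3	213	G	A	1	1	1	0.0000	0.0000	0.0154			
G2_CH3_243		IGHG2	CH3	243	G	A	1	0	1	0.0000	0.1709	0.1363			
G2_CH1_24		IGHG2	CH1	24	T	C	1	1	1			0.0320			
G2_CH1_69		IGHG2	CH1	69	A	G	1	1	1	0.0050					
G2_CH1_114		IGHG2	CH1	114	A	G	1	0	1		0.0110				
G2_CH1_159		IGHG2	CH1	159	T	C	1	1	1			0.0160			
G2_CH1_204		IGHG2	CH1	204	T	C	1	1	1	0.0210					
G2_CH1_249		IGHG2	CH1	249	G	A	1	1	1		0.0270				
G2_H_32		IGHG2	H	32	C	T	1	0	1			0.0320			
G2_CH2_41		IGHG2	CH2	41	T	C	1	1	1	0.0050					
G2_CH2_101		IGHG2	CH2	101	T	C	1	1	1		0.0110				
G2_CH2_176		IGHG2	CH2	176	C	T	1	1	0			0.0160			
G2_CH2_221		IGHG2	CH2	221	C	T	1	0	1	0.0210					
G2_CH2_266		IGHG2	CH2	266	A	G	1	1	1		0.0270				
G2_CH3_44		IGHG2	CH3	44	T	C	1	1	1	0.1130	0.0918	0.0699			
G2_CH3_104		IGHG2	CH3	104	T	C	1	1	1	0.0050					
G2_CH3_161		IGHG2	CH3	161	C	T	1	0	1	0.1600	0.2500	0.2900	0.2200	0.1700	0.1900
G2_CH3_209		IGHG2	CH3	209	A	G	1	1	1			0.0160			
G2_CH3_269		IGHG2	CH3	269	T	C	1	0	1	0.0210					
G3_CH1_224		IGHG3	CH1	224	G	A	1	1	1	0.0000	0.0335	0.0567			
G3_CH1_226		IGHG3	CH1	226	C	T	1	1	1	0.0000	0.0335	0.0567			
G3_CH2_4		IGHG3	CH2	4	C	T	1	0	1	0.0000	0.0000	0.0606			
G3_CH2_176		IGHG3	CH2	176	C	T	1	1	1	0.2500	0.1074	0.0875			
G3_CH2_191	rs12890621	IGHG3	CH2	191	A	T	1	1	1	0.6610	0.1660	0.0505			
G3_CH2_284		IGHG3	CH2	284	C	G	1	1	1	0.0000	0.0000	0.0356			
G3_CH2_319		IGHG3	CH2	319	A	G	1	1	1	0.0000	0.0335	0.0000			
G3_CH3_114		IGHG3	CH3	114	G	A	1	1	1	0.0000	0.0335	0.0923			
G3_CH3_130		IGHG3	CH3	130	G	A	1	1	1	0.2500	0.1220	0.1096			
G3_CH3_155		IGHG3	CH3	155	T	A	1	1	1	0.0890	0.1299	0.1615			
G3_CH3_168		IGHG3	CH3	168	A	G	1	1	1	0.0000	0.2105	0.2269			
G3_CH3_205		IGHG3	CH3	205	A	G	1	1	1	0.0000	0.1770	0.1500			
G3_CH3_234		IGHG3	CH3	234	C	G	1	0	1	0.0000	0.2158	0.2461			
G3_CH3_243		IGHG3	CH3	243	A	G	1	1	1	0.0000	0.1770	0.1346			
G3_CH3_283	rs4042056	IGHG3	CH3	283	G	A	1	1	1	0.0000	0.0513	0.1211			
G3_CH3_286		IGHG3	CH3	286	T	A	1	1	1	0.2500	0.1409	0.1644			
G3_CH1_24		IGHG3	CH1	24	G	A	1	1	1			0.0160			
G3_CH1_69		IGHG3	CH1	69	G	A	1	1	1	0.0210					
G3_CH1_114		IGHG3	CH1	114	G	A	1	1	1		0.0270				
G3_CH1_159		IGHG3	CH1	159	T	C	1	0	1			0.0320			
G3_CH1_204		IGHG3	CH1	204	C	T	1	1	1	0.0050					
G3_CH1_249		IGHG3	CH1	249	C	T	1	1	0		0.0110				
G3_CH1_279		IGHG3	CH1	279	G	A	1	1	1			0.0160			
G3_CH2_24		IGHG3	CH2	24	A	G	1	0	1	0.0210					
G3_CH2_69		IGHG3	CH2	69	T	C	1	1	1		0.0270				
G3_CH2_99		IGHG3	CH2	99	A	G	1	1	1			0.0320			
G3_CH2_159		IGHG3	CH2	159	A	G	1	1	1	0.0050					
G3_CH2_204		IGHG3	CH2	204	G	A	1	0	1		0.0110				
G3_CH2_249		IGHG3	CH2	249	A	G	1	1	1			0.0160			
G3_CH2_294		IGHG3	CH2	294	C	T	1	1	1	0.0210					
G3_CH3_29		IGHG3	CH3	29	G	A	1	1	1		0.0270				
G3_CH3_74		IGHG3	CH3	74	G	A	1	1	1			0.0320			
G3_CH3_149		IGHG3	CH3	149	A	G	1	1	1	0.0050					
G3_CH3_194		IGHG3	CH3	194	T	C	1	1	1		0.0110				
G3_CH3_269		IGHG3	CH3	269	T	C	1	1	1			0.0160			
G1_CH1_41		IGHG1	CH1	41	C	G	0	1	1				0.0190		
G1_CH1_245		IGHG1	CH1	245	T	C	0	1	1				0.0500		
G3_CH2_124		IGHG3	CH2	124	C	A	0	1	1						0.0120
G3_CH2_178		IGHG3	CH2	178	C	T	0	1	1					0.0100	0.0140
G1_CH3_168		IGHG1	CH3	168	G	A	0	0	1				0.2100	0.2100	0.2100
G2_CH3_313		IGHG2	CH3	313	T	C	0	0	1				0.2200	0.2200	0.2200
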