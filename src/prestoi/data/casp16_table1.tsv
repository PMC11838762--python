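target_id	difficulty	true_stoichiometry	af_max	af_avg	tb	final_top1	decision_choice	top3_correct	truth_in_candidates
H0225	10	A1B1C1	A1B1C1	A1B1C1	A1B1C1	A1B1C1	AF-max + AF-avg + TB	yes	yes
H0222	12	A1B1C1	A1B1C1	A1B1C1	A1B1C1	A1B1C1	AF-max + AF-avg + TB	yes	yes
H0223	13	A1B1C1	A1B1C1	A1B1C1	A1B1C1	A1B1C1	AF-max + AF-avg + TB	yes	yes
H0245	15	A1B1	A1B1	A1B1	NA	A1B1	AF-max + AF-avg	yes	yes
H0215	25	A1B1	A1B1	A2B2	A1B1	A1B1	AF-max + TB	yes	yes
T0206o	28	A2	A2	A2	A2	A2	AF-max + AF-avg + TB	yes	yes
T0257o	28	A3	A3	A2	A3	A3	AF-max + TB	yes	yes
T0259o	29	A3	A4	A3	NA	A3	AF-avg	yes	yes
H0208	34	A1B1	A1B1	A1B1	A2B2	A2B2	TB	yes	yes
T0240o	37	A3	A3	A2	NA	A3	AF-max	yes	yes
H0232	43	A2B2	A2B2	A2B2	A2B2	A2B2	AF-max + AF-avg + TB	yes	yes
H0272	43	A1B1C1D1E1F1G1H1I1	NA	NA	A1B1C1D1E1F1G1H1I1	A1B1C1D1E1F1G1H1I1	TB	yes	yes
H0220	47	A1B4	A1B1	A1B1	A1B4	A1B4	TB	yes	yes
T0237o	59	A4	A4	A4	NA	A4	AF-max + AF-avg	yes	yes
H0233	62	A2B2C2	A1B1C1	A1B1C1	A2B2C2	A2B2C2	TB	yes	yes
H0227	63	A1B6	NA	NA	A1B6	A1B6	TB	yes	yes
T0235o	63	A6	A6	A6	NA	A6	AF-max + AF-avg	yes	yes
T0234o	66	A3	A3	A3	NA	A3	AF-max + AF-avg	yes	yes
H0229	69	A1B1	A1B1	A2B2	NA	A2B2	AF-avg	yes	yes
H0230	69	A1B1	A2B2	A2B2	NA	A2B2	AF-max + AF-avg	yes	yes
H0217	72	A2B2C2D2E2F2	NA	NA	A2B2C2D2E2F1	A2B2C2D2E2F1	TB	no	no
H0258	75	A1B2	A1B1	A1B2	A1B2	A1B2	AF-avg + TB	yes	yes
T0218o	75	A2	A3	A3	A2	A2	TB	yes	yes
H0236	76	A3B6	A3B3	A3B3	NA	A3B3	AF-max + AF-avg	yes	yes
T0270o	78	A6	A3	A3	A6	A6	TB	yes	yes
H0244	91	A2B2C2	A2B2C1	A2B2C1	NA	A2B2C1	AF-max + AF-avg	yes	yes
H0267	93	A2B2	A1B1	A1B1	A1B1	A1B1	AF-max + AF-avg + TB	yes	yes
H0265	100	A9B18	A1B1	A1B1	NA	A1B1	AF-max + AF-avg	no	no
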