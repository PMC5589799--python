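dataset_id	patient_id	subtype	sens_expert	sens_surgery	sens_eeg	spec_expert	spec_surgery	spec_eeg	agreement
P001	1	MTLE-HS-left	1		1	1		1	1
P002	1	MTLE-HS-left	1		1	1		0
P003	2	MTLE-HS-left	1	1	0	1	1	0	0
P004	2	MTLE-HS-left	1	1	0	1	1	0
P005	2	MTLE-HS-left	1	1	0	1	1	0
P006	3	MTLE-HS-left	1		1	1		1	1
P007	4	MTLE-HS-left	1	1	1	1	1	1	1
P008	5	MTLE-HS-left	1		1	1		1	1
P009	5	MTLE-HS-left	0		0	0		0
P010	6	MTLE-HS-left	1	1	1	1	1	1	1
P011	6	MTLE-HS-left	1	1	1	1	1	1
P012	7	MTLE-HS-left	0		0	0		0	1
P013	8	MTLE-HS-left	1	1	1	1	1	1	1
P014	9	MTLE-HS-left	1			1
P015	10	MTLE-HS-left	1		1	1		1	1
P016	11	MTLE-HS-left	1		1	1		1	1
P017	12	MTLE-HS-left	1		1	1		1	1
P018	13	MTLE-HS-left	1		1	1		1	0
P019	14	MTLE-HS-right							1
P020	15	MTLE-HS-right							1
P021	16	MTLE-HS-right							1
P022	17	MTLE-HS-right	1	1	1	1	1	1	1
P023	18	MTLE-HS-right	1		1	1		1	1
P024	19	MTLE-HS-right							1
P025	20	MTLE-HS-right	0			0
P026	21	MTLE-HS-right	1			1
P027	22	MTLE-HS-right	1		0	0		0	0
P028	23	MTLE-HS-right	1			1
P029	24	LTLE-left			0			0
P030	25	LTLE-left		0	0		0	0
P031	25	LTLE-left		0	0		0	0
P032	26	LTLE-left
P033	27	LTLE-left	1		1	0		1	0
P034	27	LTLE-left	1		1	0		0
P035	27	LTLE-left	0		0	0		0
P036	28	LTLE-left	0		0	0		0	1
P037	29	LTLE-left	1			1
P038	30	LTLE-left			1			1
P039	31	LTLE-right	1		0	0		0	0
P040	32	LTLE-right	0	0	0	0	0	0	0
P041	32	LTLE-right	1	0	1	1	0	1
P042	33	LTLE-right	1	1		1	1
P043	33	LTLE-right	1	1		1	1
P044	34	LTLE-right			0			0
P045	35	LTLE-right	0			0
P046	36	LTLE-right			0			0
P047	37	LTLE-right	1		1	1		1	1
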