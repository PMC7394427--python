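patient_id	age_yrs	sex	handedness	tumor_location	tumor_size_mL	pathology
RS_003	44	M	R	Left basal ganglia	8.7	Glioblastoma
RS_003	44	M	R	Left temporal lobe	4.8	Glioblastoma
RS_004	24	M	R	Left frontal lobe	56.2	Anaplastic glioma
RS_005	36	M	NA	Left frontal lobe	1.2	Anaplastic mixed oligoastrocytoma
RS_005	36	M	NA	Left frontal lobe	0.2	Anaplastic mixed oligoastrocytoma
RS_006	36	M	NA	Left inferior frontal lobe	81.1	Anaplastic mixed oligoastrocytoma
RS_007	64	M	R	Left parieto-occipital	85.1	Glioblastoma
RS_009	65	F	R	Left peri-trigonal area	147	Glioblastoma
RS_011	24	M	R	Left frontotemporal	56.4	Mixed oligoastrocytoma
RS_012	42	M	R	Left frontal lobe	7.8	Anaplastic oligodendroglioma
RS_014	44	M	R	Left frontal/insular lobe	69.2	Oligodendroglioma
RS_015	62	F	NA	Left frontal lobe	34.7	Mixed oligoastrocytoma
RS_016	57	F	NA	Left insula	15.2	Glioblastoma
RS_017	54	M	R	Left frontal lobe	64.3	Mixed oligoastrocytoma
RS_018	39	F	R	Left frontal lobe	13.5	Oligodendroglioma
RS_019	33	F	R	Right frontoparietal	207	Anaplastic oligodendroglioma
RS_020	53	F	R	Left temporal lobe	19.9	Glioblastoma
RS_021	25	M	R	Left frontal lobe	63.3	Mixed oligoastrocytoma
RS_022	67	M	NA	Right frontal lobe	2.2	Metastatic lung carcinoma
RS_023	50	F	R	Left parietal/splenium	28.7	Oligodendroglioma
RS_024	56	M	R	Left frontal lobe	4.7	Anaplastic oligoastrocytoma
RS_027	45	M	L	Left temporal lobe	24.8	Low-grade diffuse glioma
RS_029	52	M	R	Left frontal lobe	14.5	Oligodendroglioma
RS_030	71	M	R	Right basal ganglia/thalamus	16.6	Glioblastoma
RS_031	53	F	NA	Left thalamus	5.8	Glioblastoma
RS_032	46	M	R	Right temporal lobe	5.7	Glioblastoma
RS_033	37	M	R	Left frontal lobe	185	Mixed oligoastrocytoma
RS_034	58	F	NA	Left temporal lobe	24.9	Meningioma
RS_035	28	F	R	Left temporal lobe	10.1	Oligoastrocytoma
RS_039	25	M	L	Right parietal lobe	32.0	Mixed oligoastrocytoma
RS_040	39	F	R	Right sylvian fissure	31.5	Ependymoma
RS_041	40	M	NA	Left frontal lobe	23.3	Mixed oligoastrocytoma
RS_042	60	M	R	Left parietal lobe	0.7	Glioblastoma
RS_043	33	M	R	Right temporal lobe	4.0	Low-grade glioneuronal tumor
RS_044	23	M	R	Left frontal lobe	0.4	Ganglioglioma
RS_045	28	F	L	Bilateral frontal lobes (left>right)	118	Anaplastic astrocytoma
RS_047	55	M	NA	Left frontal lobe	66.2	Glioblastoma
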