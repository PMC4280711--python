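mrna	gene_symbol	discovery_slope	discovery_p	replication_slope	replication_p
NM_005706	TSSC4	-0.00037	0.039	-0.00096	0.003
AB067498	Esco1	0.00038	0.018	0.00045	0.005
NM_018559	kiaa1704	0.00040	0.023	0.00065	0.006
NM_004897	MINPP1	0.00035	0.033	0.00070	0.006
Contig55580_RC	NA	0.00049	0.029	0.00139	0.006
NM_012180	FBXO8	0.00040	0.010	0.00067	0.014
NM_153044	MORC2-AS1	-0.00040	0.022	-0.00054	0.015
NM_022876	SMN2	0.00046	0.019	0.00083	0.017
NM_003838	FPGT	0.00035	0.031	0.00054	0.018
AF055030	PHF10	0.00036	0.011	0.00067	0.019
NM_007342	NUPL2	0.00037	0.047	0.00081	0.019
Contig45624_RC	CBLL1	0.00052	0.018	0.00091	0.020
NM_002103	GYS1	-0.00033	0.017	-0.00052	0.020
AL359938	MEIS3	-0.00029	0.040	-0.00054	0.022
NM_014771	RNF40	-0.00034	0.027	-0.00067	0.024
NM_022877	SMN2	0.00046	0.018	0.00077	0.024
Contig41498_RC	PTPN4	0.00035	0.027	0.00049	0.024
NM_003084	SNAPC3	0.00044	0.015	0.00075	0.025
NM_013234	EIF3K	-0.00025	0.044	-0.00045	0.027
NM_006852	TLK2	0.00021	0.037	0.00032	0.028
X68560	SP3	0.00065	0.012	0.00113	0.030
AY007149	CEP350	0.00034	0.029	0.00058	0.030
Contig51940_RC	GABPA	0.00046	0.035	0.00093	0.033
NM_032557	USP38	0.00048	0.017	0.00073	0.034
NM_015153	PHF3	0.00060	0.034	0.00057	0.036
NM_004162	RAB5A	0.00030	0.045	0.00048	0.037
NM_022875	SMN2	0.0004843	0.015	0.00071	0.039
NM_005316	GTF2H1	0.00042	0.010	0.00069	0.039
Contig53191_RC	GPD2	0.00043	0.043	0.00069	0.041
NM_017411	SMN2	0.00048	0.029	0.00071	0.044
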