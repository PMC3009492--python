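ptm_name	pattern
N_glycosylation	N-{P}-[ST]-{P}
O_glycosylation_mucin	[ST]-P-x-P
O_GlcNAc	P-x-[ST]-[ST]-x
C_mannosylation	W-x(2)-W
phos_PKA	R-R-x-[ST]
phos_PKG	[RK](2,3)-x-[ST]-[ILVF]
phos_PKC	[ST]-x-[RK]
phos_CK2	[ST]-x(2)-[DE]
phos_CK1	[DE]-x(2)-[ST]-x(2)-[ST]
phos_GSK3	[ST]-x(3)-[ST]-P
phos_CDK	[ST]-P-x-[RK]
phos_MAPK	P-x-[ST]-P
phos_CAMK2	R-x(2)-[ST]-[ILV]
phos_ATM_ATR	[ST]-Q-[EG]
phos_DNAPK	[ST]-Q
phos_AURORA	[RK]-x-[ST]-[ILV]
phos_PLK	[DE]-x-[ST]-[ILVFM]-x-[DE]
phos_CHK	[LIM]-x-R-x(2)-[ST]
phos_AKT	R-x-R-x(2)-[ST]
phos_RSK	R-R-x-[ST]-[ILVF]
phos_AMPK	[LIM]-x(2)-R-x(2)-[ST]
phos_NEK	[FLM]-x(2)-[ST]-[RK]
phos_IKK	[DE]-[ST]-x(2)-[DE]-[ST]
phos_CLK	R-x(2)-S-P
phos_DYRK	R-x(2)-[ST]-P
phos_PIM	[RK](3)-x-[ST]
phos_TYR_EGFR	[DE]-x(2)-Y-x(2)-[DE]
phos_TYR_INSR	Y-x(2)-M
phos_TYR_SRC	[DE](2)-x-Y
phos_TYR_ABL	[IVL]-Y-x(2)-P
phos_TYR_SYK	Y-x(2)-[LI]-x(6,8)-Y
phos_TYR_JAK	Y-x-Y
phos_generic_SP	S-P
phos_generic_TP	T-P
myristoylation	G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}
palmitoylation	C-x(2)-C-x(4)-[ILVF]
prenylation_CAAX	C-[ALIV]-[ALIV]-x>
geranylgeranylation	C-C-x(2)>
GPI_anchor	[NDSG]-[SGA]-[SGA]-x(4,8)-[FILMVW]-x(2)-[FILMVW]>
amidation	x-G-[RK]-[RK]
sulfation_TYR	[DE]-x(0,1)-Y-x(0,1)-[DE]
gamma_carboxyglutamate	E-x(2)-E-x(2)-E
hydroxylation_PRO	G-x-P-G
hydroxylation_LYS	G-x-K-G
hydroxylation_ASN	[LIVM]-x-N-x(2)-[GA]
methylation_ARG_RGG	R-G-G
methylation_ARG_RXR	R-x-R-x(2)-G
methylation_LYS	[AG]-K-[ST]-x-[GA]
methylation_CTERM	[LIVM]-x(2)-C-x(2)>
acetylation_NTERM	<M-[ADEGS]
acetylation_LYS	G-K-[ACS]
ubiquitination	[ILVF]-K-x-[DE]
sumoylation	[VIL]-K-x-[DE]-P
neddylation	[ILV]-x-K-x(2)-[DE]-[DE]
ADP_ribosylation	[RK]-x(2)-E-x(2)-[ED]
phosphopantetheine	[DEQGSTALMKRH]-[LIVMFYSTAC]-[GNQ]-[LIVMFYAG]-[DNEKHS]-S-[LIVMST]
pyridoxal_phosphate	[ST]-x-K-[LIVMFYWH]
biotinylation	[GDN]-[KAT]-[AMV]-K-[MLVI]
lipoylation	[GDE]-x(2)-[DE]-K-[AST]
flavinylation	[ST]-G-[GA]-x(2)-[SA]-C
disulfide_CXXC	C-x(2)-C
thioether_LAN	[ST]-x(2,5)-C
pyroglutamate	<Q
deamidation_NG	N-G
deamidation_NS	N-[ST]-x-[GA]
transglutamination	Q-x(2)-[PLIV]-x-G
citrullination	R-G-x-[ST]
S_nitrosylation	[ILV]-x-C-x(2)-[DE]
glutathionylation	C-x(2)-[DE]-x-[RK]
AMPylation	[HR]-x-[FY]-x(2,4)-[GN]-N
formylation	<M-x-[ST]
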