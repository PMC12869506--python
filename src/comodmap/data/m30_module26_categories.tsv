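gene	category	human_gene	cluster
Cam	none	CALM3	core
nrv3	none	ATP1B3	core
14-3-3zeta	epilepsy	YWHAG	core
Atpalpha	epilepsy	ATP1A3	core
Syt1	epilepsy_related	SYT1	core
Aldo	none	ALDOA	core
cype	none	COX6C	core
shi	epilepsy	DNM1	core
CaMKII	epilepsy_related	CAMK2B	core
Eno	none	ENO2	core
alphaSnap	epilepsy	NAPB	core
Vha68-1	epilepsy	ATP6V1A	core
shep	none	RBMS1	second
fne	none	ELAVL2	second
Sh	epilepsy	KCNA1/2	second
Snap25	epilepsy_related	SNAP25	second
stai	none	STMN2	second
Rtnl1	none	RTN1/RTN3	second
Bsg	none	NPTN	second
Rop	epilepsy	STXBP1	second
Gycalpha99B	none	GUCY1A2	second
bsk	none	MAPK8	second
Gbeta5	epilepsy_related	GNB5	second
Pgi	epilepsy_related	GPI	second
NP15.6	epilepsy_related	NDUFB11	second
veli	none	LIN7B	second
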