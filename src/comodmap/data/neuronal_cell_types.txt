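adPN
adPN/C15
adPN/C15&kn
adPN/kn
adPN/kn&CG31676
AstA/NPF
AstA/Nplp1
Capa
CCAP
CCHa1
Clock
Crz
DCN
DN1
Dopaminergic
dorsal_Fan-shaped_Body
FMRFa
Gr43a
Hsp
Hug
ITP
L1
L2
L3
L4/L5
Lamina_monopolar
Lawf1
Lawf2
LNv
lPN
lPN/CG31676
lPN/unpg
MBON
Mip
Mip/ITP
Mip/OCT
Octopaminergic
Olfactory_projection_neurons
PAM
Peptidergic
Poxn
Proc/Gpb5
Proc/Ms
Serotonergic
Tyraminergic
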