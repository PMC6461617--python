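"""Unit conversion constants. Internal computation is strictly SI; these
factors are applied only at presentation boundaries."""

KG_TO_AG = 1e21          # 1 kg = 1e21 attograms
AG_TO_KG = 1e-21
PA_TO_GPA = 1e-9
GPA_TO_PA = 1e9
HZ_PER_KG_TO_HZ_PER_AG = 1e-21
PN_TO_N = 1e-12
NM_TO_M = 1e-9
NM2_TO_M2 = 1e-18
UM_TO_M = 1e-6
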