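# energy_keV: 200
# cutoff_mrad: 5
element,sigma_nm2
H,0.0
C,0.0042
N,0.0047
O,0.0051
P,0.0165
Mg,0.0097
S,0.0182
Ca,0.0278
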