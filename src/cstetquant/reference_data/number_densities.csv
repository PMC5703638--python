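material,element,atoms_per_nm3
rrna,C,31.2
rrna,H,35.5
rrna,N,12.7
rrna,O,22.9
rrna,P,3.3
rrna,Mg,0.24
ribosome,C,19.3
ribosome,H,53.2
ribosome,N,6.86
ribosome,O,23.0
ribosome,S,0.072
ribosome,P,1.03
ribosome,Mg,0.034
tcp,Ca,18.4
tcp,P,12.2
tcp,O,49.1
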