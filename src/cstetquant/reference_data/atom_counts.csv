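material,element,count
rrna,C,68671
rrna,H,78158
rrna,N,27884
rrna,O,50462
rrna,P,7216
rrna,Mg,239
ribosome,C,135061
ribosome,H,372416
ribosome,N,48041
ribosome,O,161037
ribosome,S,501
ribosome,P,7216
ribosome,Mg,239
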