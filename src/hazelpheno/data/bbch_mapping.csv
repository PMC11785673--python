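source_code,bbch_code
61P,61P
64P,64P
67P,67P
70P,70P
71P,71P
03VP,03VP
07VP,07VP
10V,10V
13V,13V
15V,15V
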