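province,PGDP,PLO,PLA,PP,PHT,PLT,PHH,PLH
Shandong,25.9,117.0,36.4,676.5,27.8,-1.2,81.0,58.0
Guangdong,57.6,113.3,23.1,1789.3,29.1,10.5,84.0,66.0
Heilongjiang,13.7,128.0,47.9,527.1,23.4,-18.3,78.0,49.0
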