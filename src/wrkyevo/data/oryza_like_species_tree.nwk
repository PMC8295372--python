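(obra:15,(opun:6.76,(omer:4.8,(oglu:4.0,((obar:0.8,ogla:0.8)N5:2.4,(oniv:2.41,(oruf:1.2,(osaj:0.55,osai:0.55)N8:0.65)N7:1.21)N6:0.79)N4:0.8)N3:0.8)N2:1.96)N1:8.24)R;
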