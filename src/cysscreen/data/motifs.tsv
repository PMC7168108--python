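# Built-in cysteine-motif database: <motif_id>\t<family>\t<pattern>
SNA02	snakins	CX{3}CX{3}CX{8}CX{3}CX{2}CCX{2}CX{1}CX{11}CX{1}CX{12}C
LTP016	lipid-transfer	CX{7,9}CX{12,14}CCX{8,19}CX{1}CX{19,23}CX{13,15}C
HEVHIP02	hevein-like	CX{3,8}CX{4}CCX{5}CX{6}CX{3,5}CX{1,3}C
THI018	thionins	CCX{11}CX{9,15}CX{5}CX{6,11}C
CYC01	cyclotides	CX{3}CX{4}CX{6}CX{1}CX{4}C
CYC02	cyclotides	CX{3}CX{4,5}CX{4,6}CX{1}CX{4,5}C
DEF06	defensins	CX{10}CX{5}CX{3}CX{9}CX{6}CX{1}CX{3}C
DEF32	defensins	CX{4,25}CX{2,12}CX{3,4}CX{3,17}CX{4,32}CXCX{1,6}C
DEF34	defensins	CX{2,14}CX{3,5}CX{3,16}CX{4,28}CXC
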