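corpus	abstracts	region_pairs	connections	annotation
original	1377	22577	3097	manual
extension	1828	11825	2111	manual
jcn_predicted	12557	156741	28107	automatic
mscanner_predicted	8264	164555	36566	automatic
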