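descriptor	median	mean	std
weight	354.36	354.83	52.93
a_acc	5	4.99	1.41
a_don	3	2.77	1.14
b_rotN	3	3.45	1.81
logP	3.72	3.38	1.34
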