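composition	site1_os9	site1_mns4mns5	site2_os9	site2_mns4mns5	site3_os9	site3_mns4mns5
HexNAc1	3.1	3.6	1.6	2.5	0.9	0.0
Hex2HexNAc2	0.3	0.1	0.0	0.0	0.1	0.0
Hex3HexNAc2	0.6	0.3	1.0	0.7	0.6	0.0
Hex4HexNAc2	1.3	0.6	3.0	0.0	1.3	0.8
Hex5HexNAc2	1.6	1.2	2.5	4.1	2.3	1.7
Hex6HexNAc2	2.6	1.4	2.5	3.4	3.2	3.1
Hex7HexNAc2	16.4	2.8	6.9	3.2	8.4	3.2
Hex8HexNAc2	63.7	12.7	61.7	7.4	35.0	8.8
Hex9HexNAc2	5.0	56.0	9.7	58.6	19.3	36.2
Hex10HexNAc2	5.5	21.3	11.2	20.0	28.8	46.2
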