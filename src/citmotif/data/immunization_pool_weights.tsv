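offset	residue	percent
-4	G	25
-4	S	25
-4	Y	25
-4	E	25
-3	G	25
-3	D	25
-3	S	25
-3	Y	25
-2	G	25
-2	S	25
-2	Y	25
-2	E	25
-1	D	40
-1	S	40
-1	G	10
-1	E	10
1	G	40
1	D	40
1	S	10
1	A	10
2	G	40
2	D	40
2	Y	10
2	S	10
3	E	35
3	A	25
3	P	25
3	Y	15
4	G	20
4	D	20
4	Y	20
4	S	20
4	E	20
5	G	20
5	D	16
5	S	16
5	Y	16
5	A	16
5	E	16
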