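# Curated IRE apical-loop motif registry.
# Columns: motif_id, version (legacy_v1_2|new_v3), n8 (bulge base), loop_pattern
# (6 IUPAC positions N14-N19), cross_pair (N14-N18), extension (N19i-N19ii or "-").
# Rows are ordered; the row order is the tie-break rank used when interpretations tie.
motif_id	version	n8	loop_pattern	cross_pair	extension
1	legacy_v1_2	C	CAGUGN	C-G	-
2	legacy_v1_2	C	CAGAGH	C-G	-
3	legacy_v1_2	C	CUGUGY	C-G	-
4	legacy_v1_2	C	CCGUGH	C-G	-
5	legacy_v1_2	C	CCGAGA	C-G	-
6	legacy_v1_2	C	CUUAGC	C-G	-
7	legacy_v1_2	C	CAAUGC	C-G	-
8	legacy_v1_2	C	CAGGGN	C-G	-
9a	legacy_v1_2	C	UAGUAY	U-A	-
9b	new_v3	C	UAGUAR	U-A	-
10	legacy_v1_2	C	UAGGAU	U-A	-
11	legacy_v1_2	C	UAGAAY	U-A	-
12	legacy_v1_2	C	UAGCAG	U-A	-
13	legacy_v1_2	C	GAGUCR	G-C	-
14	legacy_v1_2	C	GAGCCR	G-C	-
15	legacy_v1_2	C	GAGAGK	G-G	-
16	legacy_v1_2	C	GGGAGN	G-G	-
17	legacy_v1_2	C	GAGUGW	G-G	-
18	legacy_v1_2	G	CAGUGA	C-G	-
19	new_v3	C	AAGUUN	A-U	-
20	new_v3	U	CAGUGN	C-G	-
21	new_v3	U	CAGAGN	C-G	-
22	new_v3	U	CAGUGN	C-G	CA
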