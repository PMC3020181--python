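species	gene_id	size_da	n_aa	n_cys	pattern_text	theoretical_class	common_name
A. oryzae RIB40	AO090012000143	14304	145	8	CN{8}CCN{38}CN{10}CN{5}CCN{21}C	I	RolA
A. oryzae RIB40	AO090020000588	15231	151	8	CN{7}CCN{39}CN{17}CN{5}CCN{17}C	I	New
A. niger CBS 513.88	An03g02360	12486	122	8	CN{6}CCN{32}CN{25}CN{5}CCN{4}C	I
A. niger CBS 513.88	An03g02400	13063	131	8	CN{6}CCN{31}CN{23}CN{5}CCN{6}C	Intermediate
A. niger CBS 513.88	An04g08500	14397	146	8	CN{7}CCN{39}CN{20}CN{5}CCN{17}C	I
A. niger CBS 513.88	An15g03800	13225	130	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate
A. niger CBS 513.88	An01g10940	10693	100	8	CN{14}CCN{17}CN{11}CN{7}CCN{8}C	Intermediate
A. niger CBS 513.88	An07g03340	16207	162	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I
A. niger CBS 513.88	An09g05530	20465	202	9	CN{8}CCN{33}CN{11}CN{5}CCN{16}C	Intermediate
A. niger CBS 513.88	An08g09880	9169	91	9	CN{7}CCN{16}CN{6}CN{5}CCN{10}C	Intermediate
A. niger ATCC 1015	JGI128530	10803	105	7	Fragment (similar to An07g03340)	Intermediate	(New)
A. niger ATCC 1015	JGI35683	10693	100	8	CN{14}CCN{17}CN{11}CN{7}CCN{8}C	Intermediate	(New)
A. niger ATCC 1015	JGI45683	13063	131	8	CN{6}CCN{31}CN{23}CN{5}CCN{6}C	Intermediate	(New)
A. niger ATCC 1015	JGI45685	13716	132	8	CN{6}CCN{32}CN{25}CN{5}CCN{14}C	I	(New)
A. niger ATCC 1015	JGI53462	13224	130	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate	(New)
A. niger ATCC 1015	JGI194815	14397	146	8	CN{7}CCN{39}CN{20}CN{5}CCN{17}C	I	(New)
A. niger ATCC 1015	JGI43184	20381	201	9	CN{8}CCN{33}CN{11}CN{5}CCN{16}C	Intermediate	(New)
E. nidulans FGSC A4	AN7539.2	10798	109	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate
E. nidulans FGSC A4	AN8803.2	15625	157	8	CN{7}CCN{39}CN{18}CN{5}CCN{17}C	I	RodA
E. nidulans FGSC A4	AN6401.2	16131	162	8	CN{6}CCN{38}CN{22}CN{5}CCN{35}C	Intermediate
E. nidulans FGSC A4	AN8006.2	13183	135	8	CN{6}CCN{31}CN{23}CN{5}CCN{6}C	I	DewA
E. nidulans FGSC A4	AN1837.2	13397	135	8	CN{7}CCN{39}CN{18}CN{5}CCN{17}C	I
E. nidulans FGSC A4	AN0940.2	10594	101	8	CN{13}CCN{17}CN{12}CN{7}CCN{8}C	Intermediate
A. fumigatus AF293	AFUA_8G07060	15996	155	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	RodC
A. fumigatus AF293	AFUA_5G09580	16153	159	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	RodA
A. fumigatus AF293	AFUA_2G14661	12928	125	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate	New
A. fumigatus AF293	AFUA_1G17250	14299	140	8	CN{7}CCN{36}CN{18}CN{5}CCN{18}C	I	RodB
A. fumigatus AF293	AFUA_5G03280	19825	190	9	CN{7}CCN{33}CN{11}CN{5}CCN{14}C	I	RodF
A. fumigatus A1163	AFUB_016640	14300	140	8	CN{7}CCN{36}CN{18}CN{5}CCN{18}C	I	(RodB New)
A. fumigatus A1163	AFUB_057130	16153	159	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	(RodA New)
A. fumigatus A1163	AFUB_080740	15996	155	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	(RodC New)
A. fumigatus A1163	AFUB_051810	19825	190	9	CN{7}CCN{33}CN{11}CN{5}CCN{14}C	Intermediate	(RodF New)
A. terreus NIH 2624	ATEG_10285	13978	129	8	CN{5}CCN{28}CN{14}CN{8}CCN{13}C	Intermediate	New
A. terreus NIH 2624	ATEG_08089	18936	177	8	CN{8}CCN{33}CN{11}CN{5}CCN{14}C	Intermediate	New
A. terreus NIH 2624	ATEG_07808	11677	115	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate	New
A. terreus NIH 2624	ATEG_06492	17374	175	8	CN{7}CCN{40}CN{16}CN{5}CCN{17}C	I	New
A. terreus NIH 2624	ATEG_04730	11797	121	8	CN{10}CCN{11}CN{16}CN{8}CCN{10}C	II	New
A. flavus NRRL 3357	AFLA_094600	8377	83	8	CN{7}CCN{16}CN{6}CN{5}CCN{9}C	Intermediate	New
A. flavus NRRL 3357	AFLA_131460	10867	106	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate	New
A. flavus NRRL 3357	AFLA_060780	27807	251	8	CN{6}CCN{30}CN{23}CN{5}CCN{4}C	I	New
A. flavus NRRL 3357	AFLA_014260	14304	145	8	CN{8}CCN{38}CN{10}CN{5}CCN{21}C	I	New
A. flavus NRRL 3357	AFLA_063080	9362	87	9	CN{5}CCN{17}CN{7}CN{7}CCN{12}C	Intermediate	New
A. flavus NRRL 3357	AFLA_098380	23415	217	10	CN{7}CCN{39}CN{17}CN{5}CCN{44}C	I	New
A. flavus NRRL 3357	AFLA_064900	9147	91	10	CN{7}CCN{15}CN{6}CN{5}CCN{8}C	Intermediate	New
A. clavatus NRRL 1	ACLA_001890	10214	100	8	CN{7}CCN{16}CN{6}CN{5}CCN{26}C	Intermediate	New
A. clavatus NRRL 1	ACLA_048810	18458	182	8	CN{7}CCN{33}CN{11}CN{5}CCN{15}C	Intermediate	New
A. clavatus NRRL 1	ACLA_010960	14671	145	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	New
A. clavatus NRRL 1	ACLA_072820	16127	158	8	CN{7}CCN{39}CN{21}CN{5}CCN{17}C	I	New
A. clavatus NRRL 1	ACLA_018290	12820	126	8	CN{5}CCN{32}CN{6}CN{5}CCN{13}C	Intermediate	New
A. clavatus NRRL 1	ACLA_007980	14558	144	8	CN{7}CCN{36}CN{18}CN{5}CCN{17}C	Intermediate	New
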