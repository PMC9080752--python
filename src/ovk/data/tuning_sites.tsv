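opsin_class	bovine_site	from_residue	to_residue	shift_nm	source
RH1	299	S	A	-2	site-directed mutagenesis literature (rod opsins)
SWS2	265	W	T	-29	site-directed mutagenesis literature (SWS2 pigments)
SWS2	46	F	V	8	site-directed mutagenesis literature (SWS2 pigments)
RH2	88	M	C	3	site-directed mutagenesis literature (RH2 pigments)
RH2	88	C	A	-3	site-directed mutagenesis literature (RH2 pigments)
RH2	112	I	V	1	site-directed mutagenesis literature (RH2 pigments)
RH2	266	T	V	-2	site-directed mutagenesis literature (RH2 pigments)
RH2	185	T	C	-4	site-directed mutagenesis literature (RH2 pigments)
RH2	97	T	A	-8	site-directed mutagenesis literature (RH2 pigments)
RH2	151	N	S	4	site-directed mutagenesis literature (RH2 pigments)
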