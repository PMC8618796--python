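# Phenotypic character matrix for the genus Wickerhamomyces (38 species x 22 characters).
# Cleaned transcription of the published summary table; tokens kept as printed,
# including the figure-dash negative glyph and mixed alternation separators.
species	Ga	Sor	DXy	LAr	DAr	Rh	Su	Cel	Mlb	Raf	St	Rbl	DGlu	Man	Glt	2ket	Cit	NO3	vitfree	g37C	ascoMEA	hyphae
W. alni	‒	‒	+	‒	‒	+	+	+	‒	‒	‒	v	+	+	‒	‒	+	+	‒	‒	+	‒
W. anomalus	v	‒	v	v	‒	‒	+	+	‒	+	+	v	+	+	‒	‒	+	+	+	v	+	‒
W. arborarius	+	l/‒	+	v	v	l/+	+	v	+	+	+	+	+	+	‒	n	+	+	n	‒	‒	‒
W. bisporus	‒	‒	+	w/‒	‒	+	+	+	‒	‒	‒	v	w/+	v	‒	‒	+	+	‒	‒	n	+
W. bovis	‒	‒	+	+	‒	v	+	+	‒	‒	v	‒	+	+	‒	‒	+	‒	‒	+	+	‒
W. canadensis	‒	‒	+	‒	‒	w/+	+	+	‒	‒	‒	v	+	w/+	‒	‒	+	v	‒	+	+	v
W. chambardii	+	‒	‒	‒	‒	‒	‒	+	‒	‒	‒	‒	‒	‒	‒	‒	w	‒	‒	‒	+	‒
W. chaumierensis	‒	‒	+	‒	n	‒	+	+	‒	‒	n	n	‒	‒	n	‒	n	‒	n	‒	n	‒
W. ciferrii	+	‒	w/+	w/+	‒	w/+	+	w/+	‒	+	+	+	+	+	‒	‒	+	+	+	w/‒	+	v
W. edaphicus	+	‒	+	w/‒	‒	+	+	+	+	+	+	+	+	+	l/‒	‒	+	+	+	w	n	‒
W. hampshirensis	‒	‒	+	‒	‒	s	+	+	‒	‒	‒	w/+	+	v	‒	‒	s	‒	‒	‒	+	‒
W. kurtzmanii	‒	‒	‒	‒	‒	‒	+	‒	w	‒	‒	‒	‒	w	‒	n	‒	+	‒	‒	‒	‒
W. lynferdii	+	‒	‒	‒	‒	‒	+	+	‒	+	‒	+	+	+	‒	‒	+	+	+	‒	+	‒
W. menglaensis	‒	‒	w	w	‒	w	‒	+	‒	‒	w	‒	+	+	‒	‒	+	+	+	n	‒	‒
W. mori	‒	+	‒	‒	w	‒	+	‒	‒	‒	‒	‒	n	+	‒	‒	w	‒	+	‒	‒	‒
W. mucosus	‒	+	+	‒	v	‒	+	+	‒	‒	+	‒	+	w/+	‒	+	‒	‒	‒	‒	+	‒
W. myanmarensis	+	‒	s	w	s	‒	+	s	‒	s	+	+	+	+	‒	n	+	+	+	+	+	‒
W. ochangensis	‒	‒	+	‒	‒	+	‒	+	‒	‒	‒	‒	+	+	‒	‒	‒	+	n	+	n	‒
W. onychis	‒	‒	+	v	v	‒	+	+	‒	+	‒	‒	+	+	‒	‒	+	‒	‒	+	+	‒
W. orientalis	+	n	w	w	w	w/‒	+	+	w	w	‒	w	n	w	n	n	‒	‒	‒	+	‒	+
W. patagonicus	w	‒	+	‒	‒	+	n	w	‒	w	w	‒	w	‒	‒	n	‒	‒	+	‒	n	‒
W. pijperi	‒	+	+	‒	‒	‒	‒	+	‒	‒	‒	‒	+	+	‒	‒	v	‒	‒	‒	+	‒
W. psychrolipolyticus	‒	‒	+	‒	+	+	+	+	‒	+	+	‒	+	+	n	n	+	+	n	‒	‒	‒
W. queroliae	‒	‒	+	+	‒	+	+	‒	‒	‒	‒	+	+	+	‒	‒	w/s	+	‒	+	‒	‒
W. rabaulensis	‒	‒	+	+	‒	v	+	+	‒	+	‒	+	+	+	‒	‒	+	‒	‒	+	+	‒
W. scolytoplatypi	+	‒	s	‒	‒	s	+	+	‒	‒	+	s	+	+	‒	‒	‒	+	‒	‒	+	‒
W. siamensis	s	‒	s	‒	‒	‒	+	w	‒	w	w	‒	w	w	‒	‒	‒	‒	‒	+	+	-
W. silvicola	+	v	+	+	‒	+	v	+	‒	‒	‒	+	+	v	‒	‒	v	+	‒	v	+	v
W. spegazzinii	+	‒	+	‒	‒	+	+	+	+	+	s	‒	+	+	‒	‒	w	+	+	+	+	‒
W. strasburgensis	+	‒	+	+	‒	+	+	+	‒	+	‒	+	+	+	‒	‒	+	‒	‒	v	+	‒
W. subpelliculosus	v	‒	v	v	v	‒	+	v	‒	+	v	v	+	+	‒	‒	+	+	‒	v	+	v
W. sydowiorum	+	‒	v	+	‒	+	+	+	+	+	v	+	+	+	‒	‒	+	+	+	‒	+	‒
W. sylviae	v	‒	s/‒	+	+	+,‒	w/‒	s/‒	‒	‒	w/+	s/‒	‒	‒	‒	‒	‒	v	+	+	‒	‒
W. tratensis	‒	‒	‒	‒	‒	‒	‒	v	‒	‒	‒	‒	v	v	‒	‒	‒	n	n	+	n	‒
W. xylosicus	‒	+	+	‒	‒	‒	+	+	‒	‒	‒	‒	‒	+	‒	w	‒	‒	n	‒	+	‒
W. xylosivorus	w/‒	‒	+	‒	‒	+	‒	+	‒	w	‒	‒	+	‒	n	‒	‒	+	+	n	‒	‒
W. lannaensis	‒	‒	+	‒	‒	+	‒	+	‒	‒	‒	‒	+	+	‒	‒	‒	+	w	‒	‒	‒
W. nanensis	+	‒	‒	‒	‒	‒	‒	+	‒	‒	‒	‒	‒	+	‒	‒	+	w	w	‒	‒	‒
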