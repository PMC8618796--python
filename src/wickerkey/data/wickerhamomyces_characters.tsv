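# Character vocabulary for the Wickerhamomyces phenotypic matrix.
# Codes are ASCII-normalized; labels keep the published wording.
code	label	kind
Ga	Galactose	assimilation
Sor	L-Sorbose	assimilation
DXy	D-Xylose	assimilation
LAr	L-Arabinose	assimilation
DAr	D-Arabinose	assimilation
Rh	L-Rhamnose	assimilation
Su	Sucrose	assimilation
Cel	Cellobiose	assimilation
Mlb	Melibiose	assimilation
Raf	Raffinose	assimilation
St	Soluble starch	assimilation
Rbl	Ribitol	assimilation
DGlu	D-Glucitol	assimilation
Man	D-Mannitol	assimilation
Glt	Galactitol	assimilation
2ket	2-Ketogluconic acid	assimilation
Cit	Citrate	assimilation
NO3	Potassium nitrate	assimilation
vitfree	Growth in vitamin-free medium	growth-condition
g37C	Growth at 37 °C	growth-condition
ascoMEA	Ascospores on 5% MEA	morphology
hyphae	True hyphae	morphology
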