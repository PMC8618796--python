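# identifier: W. nanensis SDBR-CMU-S2-17 (ex-type)
# Specimen profile assembled from the published species description.
character	state
Ga	+
Sor	-
DXy	-
LAr	-
DAr	-
Rh	-
Su	-
Cel	+
Mlb	-
Raf	-
St	-
Rbl	-
DGlu	-
Man	+
Glt	-
2ket	-
Cit	+
NO3	w
vitfree	w
g37C	-
ascoMEA	-
hyphae	-
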