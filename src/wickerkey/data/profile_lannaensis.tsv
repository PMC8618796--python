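# identifier: W. lannaensis SDBR-CMU-S3-15 (ex-type)
# Specimen profile assembled from the published species description:
# carbon/nitrogen sources listed as assimilated are positive, sources in the
# no-growth list negative; characters the description omits from the
# positives list (galactose) are recorded negative.
character	state
Ga	-
Sor	-
DXy	+
LAr	-
DAr	-
Rh	+
Su	-
Cel	+
Mlb	-
Raf	-
St	-
Rbl	-
DGlu	+
Man	+
Glt	-
2ket	-
Cit	-
NO3	+
vitfree	w
g37C	-
ascoMEA	-
hyphae	-
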