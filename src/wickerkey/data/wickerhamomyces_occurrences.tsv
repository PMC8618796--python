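# Global distribution and isolation sources of the 36 previously described
# Wickerhamomyces species (literature-compiled). Localities verbatim;
# obvious run-together tokens in the source were split at "and".
species	localities	source	year
W. alni	Canada	Exudate of Alnus rubra
W. anomalus	Algeria;Brazil;China;Colombia;Ethiopia;India;Iraq;King George Island;Lao;Russia;Slovakia;Sweden;Thailand	Process of beer and wine, phylloplane, soil, water, coral reefs, Thai traditional alcoholic starter, mangrove forest, fermented food, flowers, fruits, fermented grains, coffee processing, wastewater treatment plant, Colombian fermented beans and Brazilian spirit
W. arborarius	Ecuador	Flower
W. bisporus	Finland;France;USA	Platypus compositus, phoretic mites on Ips typographus and bark beetles (Dendroctonus)
W. bovis	Portugal	Caecum of feral cattle (Bos taurus)
W. canadensis	Canada	Beetle frass from Pinus resinosa
W. chambardii	France	Chestnut
W. chaumierensis	Guyana	Surface of flower
W. ciferrii	Dominican Republic;USA;Thailand	Fruit of Dipteryx odorata and male olive fruit fly (Bactrocera oleae)
W. edaphicus	India;Thailand	Forest and mangrove soils
W. hampshirensis	USA	Frass of cut and dead of Quercus and beetle (Xyloterinus politus)
W. kurtzmanii	China	Crater lake water
W. lynferdii	South Africa	Soil
W. menglaensis	China	Rotting wood
W. mori	China	Gut of larvae of wood-boring insect on trunk of Morus alba
W. mucosus	USA	Soil
W. myanmarensis	Iran;Myanmar	Palm sugar in rum distiller, and blood and central venous catheter of patients
W. ochangensis	South Korea	Soil of potato field
W. onychis	Brazil;Ethiopia;Iraq;Malaysia;Netherlands;Poland;Tunisia	Nail infection of Homo sapiens, fermented food, cocoa beans, grape and tomato during spontaneous fermentation, and soil
W. orientalis	Iran;Sri Lanka	Fruits and rhizosphere soil
W. patagonicus	Argentina	Sap exudate on cut branches of Nothofagus dombeyi and glacier meltwater river
W. pijperi	Egypt;Ghana;South Africa	Buttermilk, cocoa fermentation and orange juice
W. psychrolipolyticus	Japan	Soil
W. queroliae	Brazil	Larva of Anastrepha mucronata from fruit of Peritassa campestris
W. rabaulensis	Ethiopia;Papua New Guinea;Thailand	Excreta of snail, soils, decaying agricultural residues, decaying leaves and tree bark, and fermented food
W. scolytoplatypi	Japan	Gallery of beetles (Scolytoplatypus shogun) in Fagus crenata
W. siamensis	Thailand	Phylloplane of Saccharum officinarum
W. silvicola	Germany;South Korea;USA	Flowers, gum of Prunus serotina and Prunus wood
W. spegazzinii	Argentina	The fungus garden of an attine ant nest (Acromyrmex lundii)
W. strasburgensis	France	On leather tanned by vegetable means
W. subpelliculosus	Egypt;USA	Fermenting cucumber brines, gut of honey bee and molasses
W. sydowiorum	Brazil;Ivory Coast;South Africa;Thailand	Frass of Sinoxylon ruficorne in dead Combretum apiculatum, decayed plant leaf, fermented cocoa, honey, sand and water
W. sylviae	Italy	Cloaca of migratory birds (Sylvia communis)
W. tratensis	Thailand	Flower of mangrove apple (Sonneratia caseolaris)
W. xylosicus	Thailand	Soil
W. xylosivorus	Indonesia	Decayed wood
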