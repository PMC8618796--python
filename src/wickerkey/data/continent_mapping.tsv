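# Default place -> continent mapping (UN-style geoscheme with explicit pins
# for non-country localities and border cases: Russia -> Europe,
# Dominican Republic -> North America, King George Island -> Antarctica).
place	continent
Algeria	Africa
Argentina	South America
Brazil	South America
Canada	North America
China	Asia
Colombia	South America
Dominican Republic	North America
Ecuador	South America
Egypt	Africa
Ethiopia	Africa
Finland	Europe
France	Europe
Germany	Europe
Ghana	Africa
Guyana	South America
India	Asia
Indonesia	Asia
Iran	Asia
Iraq	Asia
Italy	Europe
Ivory Coast	Africa
Japan	Asia
King George Island	Antarctica
Lao	Asia
Malaysia	Asia
Myanmar	Asia
Netherlands	Europe
Papua New Guinea	Oceania
Poland	Europe
Portugal	Europe
Russia	Europe
Slovakia	Europe
South Africa	Africa
South Korea	Asia
Sri Lanka	Asia
Sweden	Europe
Thailand	Asia
Tunisia	Africa
USA	North America
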