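country	region
United States	North America
United States of America	North America
USA	North America
US	North America
Canada	North America
Mexico	North America
Guatemala	North America
Belize	North America
Honduras	North America
El Salvador	North America
Nicaragua	North America
Costa Rica	North America
Panama	North America
Cuba	North America
Jamaica	North America
Haiti	North America
Dominican Republic	North America
Bahamas	North America
Greenland	North America
Brazil	South America
Argentina	South America
Chile	South America
Peru	South America
Colombia	South America
Venezuela	South America
Ecuador	South America
Bolivia	South America
Paraguay	South America
Uruguay	South America
Guyana	South America
Suriname	South America
French Guiana	South America
Trinidad and Tobago	South America
United Kingdom	Europe
Great Britain	Europe
England	Europe
Scotland	Europe
Ireland	Europe
France	Europe
Germany	Europe
Spain	Europe
Portugal	Europe
Italy	Europe
Netherlands	Europe
Belgium	Europe
Switzerland	Europe
Austria	Europe
Poland	Europe
Czech Republic	Europe
Slovakia	Europe
Hungary	Europe
Romania	Europe
Bulgaria	Europe
Greece	Europe
Norway	Europe
Sweden	Europe
Finland	Europe
Denmark	Europe
Iceland	Europe
Russia	Europe
Ukraine	Europe
China	Asia
Japan	Asia
India	Asia
Mongolia	Asia
South Korea	Asia
North Korea	Asia
Vietnam	Asia
Thailand	Asia
Myanmar	Asia
Laos	Asia
Cambodia	Asia
Malaysia	Asia
Indonesia	Asia
Philippines	Asia
Taiwan	Asia
Nepal	Asia
Bhutan	Asia
Bangladesh	Asia
Sri Lanka	Asia
Pakistan	Asia
Afghanistan	Asia
Iran	Asia
Iraq	Asia
Turkey	Asia
Israel	Asia
Jordan	Asia
Saudi Arabia	Asia
Yemen	Asia
Oman	Asia
Kazakhstan	Asia
Uzbekistan	Asia
Egypt	Africa
Libya	Africa
Tunisia	Africa
Algeria	Africa
Morocco	Africa
Sudan	Africa
Ethiopia	Africa
Somalia	Africa
Kenya	Africa
Tanzania	Africa
Uganda	Africa
Rwanda	Africa
Burundi	Africa
Democratic Republic of the Congo	Africa
Republic of the Congo	Africa
Cameroon	Africa
Nigeria	Africa
Ghana	Africa
Ivory Coast	Africa
Senegal	Africa
Mali	Africa
Niger	Africa
Chad	Africa
South Africa	Africa
Namibia	Africa
Botswana	Africa
Zimbabwe	Africa
Zambia	Africa
Mozambique	Africa
Malawi	Africa
Angola	Africa
Madagascar	Africa
Gabon	Africa
Liberia	Africa
Sierra Leone	Africa
Guinea	Africa
Australia	Australasia
New Zealand	Australasia
Papua New Guinea	Australasia
Fiji	Oceania
Samoa	Oceania
Tonga	Oceania
Vanuatu	Oceania
Solomon Islands	Oceania
New Caledonia	Oceania
French Polynesia	Oceania
Micronesia	Oceania
Palau	Oceania
Marshall Islands	Oceania
Kiribati	Oceania
Guam	Oceania
Hawaii	Oceania
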