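# Default country -> region assignment (six regions).
# Transcontinental placements: Russia -> Europe, Turkey/Georgia -> Asia,
# Egypt -> Africa, Mexico + Central America + Caribbean -> North America.
# Fully overridable via a user-supplied map of the same format.

United States: North America
Canada: North America
Mexico: North America
Guatemala: North America
Belize: North America
Honduras: North America
El Salvador: North America
Nicaragua: North America
Costa Rica: North America
Panama: North America
Cuba: North America
Jamaica: North America
Haiti: North America
Dominican Republic: North America
Bahamas: North America
Barbados: North America
Trinidad and Tobago: North America
Saint Lucia: North America
Saint Vincent and the Grenadines: North America
Saint Kitts and Nevis: North America
Grenada: North America
Antigua and Barbuda: North America
Dominica: North America
Puerto Rico: North America
Bermuda: North America
Greenland: North America
Cayman Islands: North America
Guadeloupe: North America
Martinique: North America
Aruba: North America
Curacao: North America
Netherlands Antilles: North America
Virgin Islands (U.S.): North America

Brazil: South America
Argentina: South America
Chile: South America
Peru: South America
Colombia: South America
Venezuela: South America
Ecuador: South America
Bolivia: South America
Paraguay: South America
Uruguay: South America
Guyana: South America
Suriname: South America
French Guiana: South America
Falkland Islands: South America

United Kingdom: Europe
Ireland: Europe
France: Europe
Germany: Europe
Netherlands: Europe
Belgium: Europe
Luxembourg: Europe
Switzerland: Europe
Austria: Europe
Italy: Europe
Spain: Europe
Portugal: Europe
Denmark: Europe
Norway: Europe
Sweden: Europe
Finland: Europe
Iceland: Europe
Poland: Europe
Czech Republic: Europe
Slovakia: Europe
Hungary: Europe
Romania: Europe
Bulgaria: Europe
Greece: Europe
Croatia: Europe
Slovenia: Europe
Serbia: Europe
Bosnia and Herzegovina: Europe
Montenegro: Europe
North Macedonia: Europe
Albania: Europe
Kosovo: Europe
Estonia: Europe
Latvia: Europe
Lithuania: Europe
Belarus: Europe
Ukraine: Europe
Moldova: Europe
Russia: Europe
Malta: Europe
Cyprus: Europe
Monaco: Europe
Andorra: Europe
San Marino: Europe
Liechtenstein: Europe
Vatican City: Europe
Gibraltar: Europe
Faroe Islands: Europe
Isle of Man: Europe
Jersey: Europe
Guernsey: Europe

Turkey: Asia
Georgia: Asia
Armenia: Asia
Azerbaijan: Asia
Kazakhstan: Asia
Uzbekistan: Asia
Turkmenistan: Asia
Kyrgyzstan: Asia
Tajikistan: Asia
China: Asia
Japan: Asia
South Korea: Asia
North Korea: Asia
Taiwan: Asia
Hong Kong: Asia
Macau: Asia
Mongolia: Asia
India: Asia
Pakistan: Asia
Bangladesh: Asia
Sri Lanka: Asia
Nepal: Asia
Bhutan: Asia
Maldives: Asia
Afghanistan: Asia
Iran: Asia
Iraq: Asia
Syria: Asia
Lebanon: Asia
Israel: Asia
Palestine: Asia
Jordan: Asia
Saudi Arabia: Asia
Yemen: Asia
Oman: Asia
United Arab Emirates: Asia
Qatar: Asia
Bahrain: Asia
Kuwait: Asia
Vietnam: Asia
Laos: Asia
Cambodia: Asia
Thailand: Asia
Myanmar: Asia
Malaysia: Asia
Singapore: Asia
Indonesia: Asia
Brunei: Asia
Philippines: Asia
Timor-Leste: Asia

Egypt: Africa
Libya: Africa
Tunisia: Africa
Algeria: Africa
Morocco: Africa
Western Sahara: Africa
Mauritania: Africa
Mali: Africa
Niger: Africa
Chad: Africa
Sudan: Africa
South Sudan: Africa
Eritrea: Africa
Djibouti: Africa
Ethiopia: Africa
Somalia: Africa
Senegal: Africa
Gambia: Africa
Guinea-Bissau: Africa
Guinea: Africa
Sierra Leone: Africa
Liberia: Africa
Ivory Coast: Africa
Ghana: Africa
Togo: Africa
Benin: Africa
Nigeria: Africa
Cameroon: Africa
Central African Republic: Africa
Equatorial Guinea: Africa
Gabon: Africa
Republic of the Congo: Africa
Democratic Republic of the Congo: Africa
Uganda: Africa
Kenya: Africa
Rwanda: Africa
Burundi: Africa
Tanzania: Africa
Angola: Africa
Zambia: Africa
Malawi: Africa
Mozambique: Africa
Zimbabwe: Africa
Botswana: Africa
Namibia: Africa
South Africa: Africa
Lesotho: Africa
Eswatini: Africa
Madagascar: Africa
Comoros: Africa
Mauritius: Africa
Seychelles: Africa
Cabo Verde: Africa
Sao Tome and Principe: Africa
Reunion: Africa
Burkina Faso: Africa

Australia: Oceania
New Zealand: Oceania
Papua New Guinea: Oceania
Fiji: Oceania
Solomon Islands: Oceania
Vanuatu: Oceania
Samoa: Oceania
American Samoa: Oceania
Tonga: Oceania
Kiribati: Oceania
Tuvalu: Oceania
Nauru: Oceania
Palau: Oceania
Marshall Islands: Oceania
Micronesia: Oceania
New Caledonia: Oceania
French Polynesia: Oceania
Guam: Oceania
Northern Mariana Islands: Oceania
Cook Islands: Oceania
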