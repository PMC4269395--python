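# Default alias -> canonical country name table.
# Keys are matched case-insensitively after whitespace trimming.
# Canonical names themselves always resolve to themselves (identity entries
# are added programmatically from the region map), so only variants that
# differ from the canonical spelling need to be listed here.

"United States of America": United States
"USA": United States
"U.S.A.": United States
"US": United States
"United Kingdom of Great Britain and Northern Ireland": United Kingdom
"UK": United Kingdom
"Great Britain": United Kingdom
"Korea, Republic of": South Korea
"Republic of Korea": South Korea
"Korea, Democratic People's Republic of": North Korea
"Russian Federation": Russia
"Iran, Islamic Republic of": Iran
"Syrian Arab Republic": Syria
"Taiwan, Province of China": Taiwan
"Viet Nam": Vietnam
"Lao People's Democratic Republic": Laos
"Moldova, Republic of": Moldova
"Republic of Moldova": Moldova
"Macedonia, The Former Yugoslav Republic of": North Macedonia
"Former Yugoslav Republic of Macedonia": North Macedonia
"Macedonia": North Macedonia
"Libyan Arab Jamahiriya": Libya
"Tanzania, United Republic of": Tanzania
"United Republic of Tanzania": Tanzania
"Congo, The Democratic Republic of the": Democratic Republic of the Congo
"Congo, Democratic Republic of the": Democratic Republic of the Congo
"Congo": Republic of the Congo
"Cote d'Ivoire": Ivory Coast
"Côte d'Ivoire": Ivory Coast
"Cote D'Ivoire": Ivory Coast
"Brunei Darussalam": Brunei
"Cape Verde": Cabo Verde
"Czechia": Czech Republic
"Holy See (Vatican City State)": Vatican City
"Holy See": Vatican City
"Palestinian Territory, occupied": Palestine
"Palestinian Territories, Occupied": Palestine
"Occupied Palestinian Territory": Palestine
"Burma": Myanmar
"Swaziland": Eswatini
"East Timor": Timor-Leste
"The Netherlands": Netherlands
"Netherlands, The": Netherlands
"Gambia, The": Gambia
"The Gambia": Gambia
"Bahamas, The": Bahamas
"Bolivia, Plurinational State of": Bolivia
"Venezuela, Bolivarian Republic of": Venezuela
"Micronesia, Federated States of": Micronesia
"Federated States of Micronesia": Micronesia
"Saint Vincent and The Grenadines": Saint Vincent and the Grenadines
"Virgin Islands, U.S.": Virgin Islands (U.S.)
"Slovak Republic": Slovakia
"Kyrgyz Republic": Kyrgyzstan
"Curaçao": Curacao
"Réunion": Reunion
"Falkland Islands (Malvinas)": Falkland Islands
"Macao": Macau
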