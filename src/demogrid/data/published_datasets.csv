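name,description,format,resolution,dataverse_doi
AFR_2010_SubNat_DepRatio,"Subnational combined (CDR), young (YDR) and old (ODR) dependency ratio datasets for 50 African countries",GeoTIFF,30 arc seconds,10.7910/DVN/S5JHQN
ASIA_2010_SubNat_DepRatio,"Subnational combined (CDR), young (YDR) and old (ODR) dependency ratio datasets for 37 Asian countries",GeoTIFF,30 arc seconds,10.7910/DVN/6TPPZ8
AFR_PPP_AGE_2010,"Female/male per pixel, per 5-year age group from 00-04 to 65+, for 50 African countries in 2010; country totals adjusted to match 2010 UN national estimates",GeoTIFF,30 arc seconds,10.7910/DVN/4MJN3G
ASIA_PPP_AGE_2010,"Female/male per pixel, per 5-year age group from 00-04 to 65+, for 37 Asian countries in 2010; country totals adjusted to match 2010 UN national estimates",GeoTIFF,30 arc seconds,10.7910/DVN/GUSJUZ
WP_DemographicData_CountryMask,"Numeric ISO-3166 country codes for all 87 African and Asian countries covered",GeoTIFF,30 arc seconds,"10.7910/DVN/S5JHQN, 10.7910/DVN/6TPPZ8, 10.7910/DVN/4MJN3G, 10.7910/DVN/GUSJUZ"
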