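country,continent,data_type,year,admin_level,source
Afghanistan,Asia,DHS,2010,1,"MEASURE Demographic and Health Surveys, USAID"
Armenia,Asia,Census microdata,2001,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Azerbaijan,Asia,DHS,2006,1,"MEASURE Demographic and Health Surveys, USAID"
Bangladesh,Asia,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
Bhutan,Asia,Census,2005,2,"National Statistics Bureau, Bhutan"
Brunei Darussalam,Asia,UN,2010,0,"World Population Prospects, United Nations Population Division"
Cambodia,Asia,Census,2010,2,"United States Census Bureau, USAID"
China,Asia,Census,2010,3,National Bureau of Statistics of the People's Republic of China
Georgia,Asia,MICS,2005,1,"MEASURE Demographic and Health Surveys, USAID"
India,Asia,Census,2010,1,"United States Census Bureau, USAID"
Indonesia,Asia,Census,2010,1,"United States Census Bureau, USAID"
Iran,Asia,Census microdata,2006,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Iraq,Asia,Census microdata,1997,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Kazakhstan,Asia,MICS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
"Korea, Democratic People's Republic of",Asia,Census,2010,1,"National Bureau of Statistics, North Korea"
Kyrgyz Republic,Asia,Census microdata,1999,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Laos,Asia,SIS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Malaysia,Asia,Census microdata,2000,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Mongolia,Asia,Census microdata,2000,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Myanmar,Asia,UN,2010,0,"World Population Prospects, United Nations Population Division"
Nepal,Asia,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
Pakistan,Asia,Census microdata,1998,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Papua New Guinea,Asia,UN,2010,0,"World Population Prospects, United Nations Population Division"
Philippines,Asia,Census microdata,2000,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Russia,Asia,Census,2010,1,"United States Census Bureau, USAID"
Singapore,Asia,Census,2010,2,"Statistics Singapore, Singapore"
Solomon Islands,Asia,Census,2009,1,"Solomon Islands National Statistics Office, Solomon Islands"
South Korea,Asia,Census,2010,1,"Statistics Korea, South Korea"
Sri Lanka,Asia,UN,2010,0,"World Population Prospects, United Nations Population Division"
Tajikistan,Asia,DHS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Thailand,Asia,Census,2010,2,"United States Census Bureau, USAID"
Timor-Leste,Asia,DHS,2010,1,"MEASURE Demographic and Health Surveys, USAID"
Turkey,Asia,DHS,1998,1,"MEASURE Demographic and Health Surveys, USAID"
Turkmenistan,Asia,UN,2010,0,"World Population Prospects, United Nations Population Division"
Uzbekistan,Asia,DHS,1996,1,"MEASURE Demographic and Health Surveys, USAID"
Vanuatu,Asia,Census,2009,1,"Vanuatu National Statistics Office (VNSO), Vanuatu"
Vietnam,Asia,Census microdata,2009,2,"Integrated Public Use Microdata Series, International (IPUMSI)"
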