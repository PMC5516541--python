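country,continent,data_type,year,admin_level,source
Algeria,Africa,Census,2008,1,"Office National des Statistique, Algeria"
Angola,Africa,MIS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
Benin,Africa,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
Botswana,Africa,Census,2006,2,"Central Statistics Office, Botswana"
Burkina Faso,Africa,Census,2006,1,"Institut National de la Statistique et de la Demographie (INSD), Burkina Faso"
Burundi,Africa,DHS,2010,1,"MEASURE Demographic and Health Surveys, USAID"
Cameroon,Africa,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
Central African Republic,Africa,MICS,2006,1,UNICEF
Chad,Africa,DHS,2004,1,"MEASURE Demographic and Health Surveys, USAID"
Congo,Africa,AIS,2009,1,"MEASURE Demographic and Health Surveys, USAID"
"Congo, Democratic Republic",Africa,DHS,2013,1,"MEASURE Demographic and Health Surveys, USAID"
Cote d'Ivoire,Africa,AIS,2005,1,"MEASURE Demographic and Health Surveys, USAID"
Djibouti,Africa,MICS,2006,1,UNICEF
Egypt,Africa,Census microdata,2006,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Equatorial Guinea,Africa,UN,2010,0,"World Population Prospects, United Nations Population Division"
Eritrea,Africa,UN,2010,0,"World Population Prospects, United Nations Population Division"
Ethiopia,Africa,Census,2007,1,Central Statistical Agency of Ethiopia
Gabon,Africa,DHS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Gambia,Africa,MICS,2006,1,"MEASURE Demographic and Health Surveys, USAID"
Ghana,Africa,Census,2010,2,"United States Census Bureau, USAID"
Guinea,Africa,DHS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Guinea-Bissau,Africa,MICS,2006,1,UNICEF
Kenya,Africa,Census,2010,1,"United States Census Bureau, USAID"
Lesotho,Africa,Census,2004,1,Lesotho Bureau of Statistics
Liberia,Africa,Census,2008,1,Liberia Institute of Statistics and Geo-Information Service
Libya,Africa,UN,2010,0,"World Population Prospects, United Nations Population Division"
Madagascar,Africa,DHS,2009,1,"MEASURE Demographic and Health Surveys, USAID"
Malawi,Africa,Census,2008,2,"National Statistical Office, Malawi"
Mali,Africa,DHS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Mauritania,Africa,MICS,2007,1,UNICEF
Morocco,Africa,Census,2004,2,"Haut Commissariat au Plan, Morocco"
Mozambique,Africa,Census,2007,2,"Instituto Nacional de Estatistica, Mozambique"
Namibia,Africa,Census,2010,2,"United States Census Bureau, USAID"
Niger,Africa,DHS,2012,1,"MEASURE Demographic and Health Surveys, USAID"
Nigeria,Africa,Census,2006,1,"National Bureau of Statistics, Nigeria"
Rwanda,Africa,Census,2010,2,"United States Census Bureau, USAID"
Senegal,Africa,Census microdata,2002,2,"Integrated Public Use Microdata Series, International (IPUMSI)"
Sierra Leone,Africa,Census,2004,2,Statistics Sierra Leone
Somalia,Africa,MICS,2006,1,UNICEF
South Africa,Africa,Census,2010,3,"United States Census Bureau, USAID"
South Sudan,Africa,Census microdata,2008,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Sudan,Africa,Census microdata,2008,1,"Integrated Public Use Microdata Series, International (IPUMSI)"
Swaziland,Africa,DHS,2007,1,"MEASURE Demographic and Health Surveys, USAID"
Togo,Africa,DHS,2013,1,"MEASURE Demographic and Health Surveys, USAID"
Tunisia,Africa,Census,2004,1,"National Statistics Institute, Tunisia"
Uganda,Africa,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
United Rep. of Tanzania,Africa,Census,2010,2,"United States Census Bureau, USAID"
Western Sahara,Africa,UN,2010,0,"World Population Prospects, United Nations Population Division"
Zambia,Africa,Census,2010,3,"United States Census Bureau, USAID"
Zimbabwe,Africa,DHS,2011,1,"MEASURE Demographic and Health Surveys, USAID"
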