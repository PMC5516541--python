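NAME,ADM_NAME,MPROP,FPROP,A0004,A0509,A1014,A1519,A2024,A2529,A3034,A65PL
Bhutan,BUMTHANG,54.3,45.7,8.5,9.9,12.4,12.1,12.1,9.2,6.4,6.2
Bhutan,CHHUKHA,56.9,43.1,9.4,10.5,10.7,10.6,13.4,11.7,8.2,2.6
Bhutan,TSIRANG,51.0,49.0,10.4,10.6,12.9,11.9,9.7,7.9,5.9,5.4
Bhutan,DAGANA,50.3,49.7,11.1,13.1,14.4,12.4,8.0,7.1,5.9,4.6
Bhutan,GASA,52.5,47.5,10.4,11.5,10.8,9.1,10.5,9.4,7.8,5.4
Bhutan,SARPANG,52.1,47.9,10.6,11.7,12.0,11.4,11.1,9.4,6.9,3.7
Bhutan,HAA,53.9,46.1,8.5,10.6,12.6,12.8,10.1,9.0,6.9,4.9
Bhutan,LHUENTSE,50.2,49.8,10.3,12.8,12.4,12.4,7.5,7.7,5.8,6.8
Bhutan,MONGGAR,50.4,49.6,10.3,11.8,12.8,12.8,9.0,7.8,6.2,5.6
Bhutan,PARO,53.0,47.0,8.4,10.0,11.4,11.9,12.6,9.6,7.1,5.3
Bhutan,PEMAGATSHEL,49.5,50.5,9.8,11.3,12.6,13.6,7.4,6.5,4.6,8.1
Bhutan,PUNAKHA,50.7,49.3,9.7,11.6,11.8,14.8,9.1,7.5,6.0,5.4
Bhutan,SAMTSE,52.1,47.9,10.0,11.3,12.5,10.8,10.6,8.7,6.8,4.9
Bhutan,SAMDRUPJONGKHAR,51.4,48.6,10.6,11.8,12.8,11.0,9.3,8.4,6.3,4.9
Bhutan,ZHEMGANG,50.9,49.1,9.7,11.6,14.0,13.6,8.8,6.7,5.4,6.5
Bhutan,TRASHIYANGTSE,49.9,50.1,10.9,12.4,13.0,12.3,8.1,6.8,5.4,5.3
Bhutan,TRASHIGANG,51.0,49.0,9.9,11.9,13.1,13.1,9.4,6.9,5.7,5.6
Bhutan,THIMPHU,54.2,45.8,9.6,9.6,10.9,11.6,15.3,11.4,7.9,3.0
Bhutan,TRONGSA,51.2,48.8,9.9,11.8,12.5,11.6,9.2,8.1,6.1,6.9
Bhutan,WANGDUE,51.7,48.3,10.1,11.5,12.3,11.3,10.1,8.1,6.6,5.7
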