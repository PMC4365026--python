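country,center,crc_cases,person_years_1000,fiber_mean,fiber_sd,fiber_cal_mean,fiber_cal_sd
Greece,Greece,61,99.1,23.8,7.0,23.7,3.0
Spain,Granada,29,30.9,26.0,8.2,23.7,4.7
Spain,Murcia,18,21.1,31.1,9.0,28.7,5.2
Spain,Navarra,33,33.3,28.5,7.9,25.5,4.6
Spain,San Sebastian,43,49.0,29.4,9.0,28.1,5.3
Spain,Asturias,62,48.7,24.7,7.5,25.4,4.7
Italy,Ragusa,21,31.6,28.4,9.2,25.3,4.1
Italy,Naples,36,34.9,23.8,7.3,27.4,3.6
Italy,Florence,89,69.7,21.9,7.0,25.4,3.4
Italy,Turin,27,22.7,22.0,7.0,24.0,3.4
Italy,Varese,61,99.1,23.8,7.0,23.7,3.0
Germany,Heidelberg,127,112.9,21.3,7.2,21.5,4.4
Germany,Potsdam,138,95.6,24.1,7.0,22.9,4.2
Netherlands,Bilthoven,82,115.7,26.1,7.8,26.2,7.0
United Kingdom,Oxford Health conscious,68,114.6,27.1,10.1,30.8,6.1
United Kingdom,Oxford General population,20,19.8,22.2,7.8,21.5,4.2
United Kingdom,Cambridge,236,117.7,21.8,7.6,19.4,4.7
Denmark,Copenhagen,346,196.1,25.8,8.5,25.3,5.4
Denmark,Aarhus,129,88.6,26.1,8.2,27.2,5.3
Sweden,Malmo,231,130.6,21.1,7.3,17.6,3.4
Sweden,Umea,108,159.0,21.2,8.1,20.4,3.6
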