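country,center,crc_cases,person_years_1000,fiber_mean,fiber_sd,fiber_cal_mean,fiber_cal_sd
Greece,Greece,44,148.6,20.4,6.1,17.3,2.0
Spain,Granada,27,69.1,20.0,6.3,17.8,2.9
Spain,Murcia,39,72.9,25.9,7.8,24.0,3.5
Spain,Navarra,30,52.2,22.3,6.4,19.0,3.1
Spain,San Sebastian,25,51.0,23.2,7.4,21.8,3.5
Spain,Asturias,23,54.4,20.6,6.8,19.2,3.2
Italy,Ragusa,16,33.9,24.0,8.6,18.2,3.2
Italy,Naples,28,56.4,27.0,7.2,18.0,2.9
Italy,Florence,86,101.7,21.1,6.8,20.3,2.7
Italy,Turin,41,50.2,20.0,6.5,20.2,2.6
Italy,Varese,74,99.3,19.4,6.2,18.7,2.5
France,South coast of France,64,94.1,23.1,7.3,20.6,3.0
France,South of France,116,177.4,23.1,7.1,20.1,3.0
France,North-West of France,64,112.2,22.7,6.8,18.9,2.8
France,North-East of France,179,315.6,22.2,6.8,20.0,2.8
Germany,Heidelberg,75,130.4,19.6,6.4,19.7,3.6
Germany,Potsdam,97,141.7,21.9,6.3,20.9,3.4
Netherlands,Bilthoven,52,137.2,22.0,5.8,18.8,5.2
Netherlands,Utrecht,253,178.5,21.9,5.4,21.8,4.2
United Kingdom,Oxford Health conscious,181,385.4,25.6,9.3,24.4,4.2
United Kingdom,Oxford General population,32,58.2,22.3,7.6,17.6,3.5
United Kingdom,Cambridge,191,142.7,22.4,7.6,16.8,3.5
Denmark,Copenhagen,250,224.4,24.1,8.0,22.3,5.1
Denmark,Aarhus,103,92.3,24.4,7.8,24.6,5.0
Sweden,Malmo,219,187.4,18.7,6.1,15.4,2.5
Sweden,Umea,94,161.9,18.9,6.8,17.5,2.6
Norway,South-East of Norway,117,188.8,20.4,6.1,18.8,2.8
Norway,North-West of Norway,93,153.5,20.7,6.0,18.8,2.8
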