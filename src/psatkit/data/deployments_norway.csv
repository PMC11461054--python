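tag_id,psat_id,tagging_date,tagging_lat,tagging_lon,cfl_cm,popup_date,popup_lat,popup_lon,duration_days,status,popup_reason,farm_capture
5120082,20P1207,2020-08-31,62.5,5.5,252,2021-06-04,45.2,-20.4,278,transmitted,pin broke,0
5120083,20P1161,2020-09-19,61.5,4.3,244,2021-09-19,61.5,4.3,366,recovered,interval,0
5120084,20P1200,2020-09-28,61.5,4.5,250,2021-09-28,61.5,4.2,366,recovered,interval,0
5120085,20P1160,2020-09-29,61.4,4.3,266,2021-01-02,43.7,-18.7,96,few transmissions,too deep,0
5120086,20P1191,2020-09-29,61.4,4.3,250,2021-09-29,58.7,5.3,369,recovered,interval,0
5120087,20P2966,2021-08-30,62.5,5.5,253,2021-09-02,62.5,5.5,4,recovered,mortality,0
5121086,20P2993,2021-09-16,62.3,4.5,242,2022-07-22,52.5,-14.1,310,transmitted,tag failure,0
5121087,20P2985,2021-09-16,62.3,4.5,290,2022-09-16,62.3,3.8,367,recovered,interval,0
5121088,20P2988,2021-09-16,62.6,5.3,270,2022-09-16,62.6,3.3,367,recovered,interval,0
5121089,20P2968,2021-09-29,62.2,4.8,243,,,,,never transmitted,,0
5121090,21P0041,2021-09-29,62.2,4.8,292,2022-09-29,63.9,1.4,366,transmitted,interval,0
5121091,21P0055,2021-09-29,62.2,4.8,275,2022-09-29,64.0,6.2,366,transmitted,interval,0
5121092,21P0051,2021-09-30,62.4,5.0,244,2022-04-20,34.0,-11.5,203,transmitted,predation,0
5121093,21P0049,2021-10-06,60.8,4.5,275,2022-10-06,61.2,2.7,366,recovered,interval,0
5122081,21P2007,2022-09-01,62.4,5.2,250,2023-09-01,37.8,-0.7,366,recovered,interval,1
5122082,21P2006,2022-09-05,61.1,4.4,280,,,,,never transmitted,,0
5122083,21P2005,2022-09-11,62.3,5.0,228,2023-09-11,57.9,6.2,366,recovered,interval,0
5122084,21P2010,2022-09-11,62.3,5.0,240,2023-09-11,62.6,5.3,366,recovered,interval,0
5122085,21P2016,2022-09-23,61.5,4.4,250,,,,,never transmitted,,0
5122086,21P0046,2022-09-23,61.6,4.4,283,2023-09-23,62.4,2.9,366,recovered,interval,0
5122087,21P0047,2022-09-24,62.1,4.9,248,2023-09-24,36.0,14.5,366,few transmissions,interval,1
5122088,21P0042,2022-09-24,62.1,4.9,237,2023-09-24,62.4,4.6,366,recovered,interval,0
5122089,21P0048,2022-09-24,62.2,4.8,251,2023-09-24,63.8,7.8,366,recovered,interval,0
5122090,21P0053,2022-09-28,61.4,4.4,254,2023-09-28,61.2,4.3,366,recovered,interval,0
5122091,21P0045,2022-09-29,62.6,5.3,277,2023-09-29,35.8,14.7,366,transmitted,interval,1
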