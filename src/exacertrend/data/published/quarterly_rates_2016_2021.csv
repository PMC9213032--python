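year,week_start,week_end,patients_at_start,episodes,rate,ci_lo,ci_hi
2016,1,13,100362,22271,88.9,83.4,94.4
2016,14,26,100045,15019,60.2,57.1,63.3
2016,27,39,99473,13455,54.2,49.8,58.5
2016,40,52,99137,20956,84.7,78.6,90.7
2017,1,13,98893,19785,80.3,72.3,88.2
2017,14,26,98362,13098,53.3,50.7,56.0
2017,27,39,98081,13191,53.9,49.9,57.9
2017,40,52,97769,19773,81.1,73.6,88.7
2018,1,13,97177,20004,82.5,73.8,91.2
2018,14,26,96655,12780,53.0,50.8,55.2
2018,27,39,95890,11623,48.7,44.6,52.8
2018,40,53,95033,17851,70.2,65.3,75.2
2019,1,13,93880,16833,72.3,66.6,78.0
2019,14,26,91680,11540,50.7,48.3,53.1
2019,27,39,90078,11342,51.2,46.7,55.6
2019,40,52,87396,15567,73.8,68.5,79.0
2020,1,13,79414,14307,73.2,67.0,79.5
2020,14,26,76870,6207,32.7,31.0,34.4
2020,27,39,74668,5183,28.0,25.6,30.3
2020,40,52,73243,6043,33.8,31.5,36.2
2021,1,13,68812,4884,29.4,27.1,31.6
2021,14,26,65194,3493,23.0,21.6,24.4
2021,27,39,58776,3185,24.4,22.6,26.3
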