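ENV,GREEN_MEAN,GREEN_CV,YELLOW_MEAN,YELLOW_CV,WINTER_MEAN,WINTER_CV
DA2012,2.9,9.2,,,2.8,19.0
DA2013,2.2,9.5,,,,
DA2014,0.9,11.2,,,1.2,19.2
DA2015,1.5,9.5,,,,
DA2016,2.3,9.2,,,,
DA2017,1.5,10.2,,,1.1,19.8
DA2018,0.9,11.4,,,2.1,19.4
DA2019,2.0,9.8,,,1.3,22.4
DA2020,2.3,10.7,,,,
FF2012,4.0,9.0,4.0,8.6,,
FF2013,2.9,9.4,3.7,9.5,,
FF2014,2.9,8.6,3.3,9.4,,
FF2015,2.2,8.5,2.1,10.0,,
FF2016,4.9,9.6,4.9,8.2,,
FF2017,2.6,9.1,3.7,9.7,,
FF2018,2.8,8.8,3.1,8.7,,
FF2019,3.2,9.8,3.4,8.7,,
FF2020,4.4,9.0,5.3,9.4,,
FF2021,1.1,10.1,2.1,10.0,,
GE2012,3.7,9.6,4.1,7.8,,
GE2014,2.2,9.0,3.0,8.2,1.5,20.5
GE2015,2.2,8.5,2.3,9.9,,
GE2016,3.3,10.2,,,4.7,18.6
GE2017,2.7,14.7,1.6,20.4,,
GE2018,4.6,8.9,,,,
GE2019,3.9,9.4,,,4.0,18.3
GE2020,3.5,9.6,,,,
GF2012,2.2,9.8,2.5,8.9,4.6,19.2
PU2012,3.2,9.3,3.3,8.5,3.7,18.6
PU2013,3.4,9.1,3.4,7.8,1.7,20.4
PU2014,1.8,10.5,1.7,10.8,3.1,20.2
PU2015,0.7,11.3,0.7,20.4,,
PU2016,2.4,9.3,2.4,8.2,3.9,19.5
PU2017,1.7,9.1,1.5,10.1,4.0,18.9
PU2018,3.5,8.9,3.6,9.0,4.0,20.2
PU2019,2.1,9.7,2.8,10.4,2.4,20.0
PU2020,4.0,8.8,4.8,8.6,5.6,18.8
PU2021,1.8,9.5,1.5,12.6,,
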