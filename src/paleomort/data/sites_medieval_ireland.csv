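site,period,date_range_ce,female,male,total
Dooey,early,6th-8th centuries,26,21,47
Owenbristy,early,6th-10th centuries,12,22,34
Carrowkeel,early,7th-11th centuries,7,9,16
Toureen Peakaun,late,7th-12th centuries,0,2,2
Bakehouse Lane,late,12th-16th centuries,19,16,35
Naas,late,13th-14th centuries,3,7,10
Ballinderry,late,13th-14th centuries,38,29,67
Tintern Abbey,late,13th-16th centuries,17,25,42
Crosse's Green,late,13th-16th centuries,35,37,72
Castledermot,late,14th-16th centuries,4,6,10
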