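litter_id,organ,flooding,time_days,dry_mass_g,C_g_per_kg,N_g_per_kg
root-LO-r1,root,LO,0.0,6.0,430.0,20.0
root-LO-r1,root,LO,365.0,2.892442608657337,399.5917254424473,23.136012917967214
root-LO-r2,root,LO,0.0,6.0,430.0,20.0
root-LO-r2,root,LO,365.0,2.9307704143769193,394.3659752626377,22.83344653340989
root-LO-r3,root,LO,0.0,6.0,430.0,20.0
root-LO-r3,root,LO,365.0,2.9268661864286263,394.8920309701434,22.863904700757942
root-LO-r4,root,LO,0.0,6.0,430.0,20.0
root-LO-r4,root,LO,365.0,2.876698646460577,401.7786618555626,23.2626346317892
rhizome-LO-r1,rhizome,LO,0.0,6.0,490.0,7.0
rhizome-LO-r1,rhizome,LO,365.0,3.7220527328031063,473.8493927280915,7.552618258102328
rhizome-LO-r2,rhizome,LO,0.0,6.0,490.0,7.0
rhizome-LO-r2,rhizome,LO,365.0,3.7134882779005896,474.94223628942865,7.570036936613415
rhizome-LO-r3,rhizome,LO,0.0,6.0,490.0,7.0
rhizome-LO-r3,rhizome,LO,365.0,3.7544453507209146,469.76111313007334,7.487455749486562
rhizome-LO-r4,rhizome,LO,0.0,6.0,490.0,7.0
rhizome-LO-r4,rhizome,LO,365.0,3.731083476009918,472.702484005211,7.534337842650208
root-ME-r1,root,ME,0.0,6.0,430.0,20.0
root-ME-r1,root,ME,365.0,1.9497488542551862,381.1504222724554,24.89311280887831
root-ME-r2,root,ME,0.0,6.0,430.0,20.0
root-ME-r2,root,ME,365.0,1.899543244882218,391.2243646607158,25.5510467101606
root-ME-r3,root,ME,0.0,6.0,430.0,20.0
root-ME-r3,root,ME,365.0,1.9656117496119385,378.0744591455136,24.692220214667362
root-ME-r4,root,ME,0.0,6.0,430.0,20.0
root-ME-r4,root,ME,365.0,1.933428172397132,384.3678341581316,25.103243487850804
rhizome-ME-r1,rhizome,ME,0.0,6.0,490.0,7.0
rhizome-ME-r1,rhizome,ME,365.0,2.895231902976212,459.9186600461627,7.785627500380347
rhizome-ME-r2,rhizome,ME,0.0,6.0,490.0,7.0
rhizome-ME-r2,rhizome,ME,365.0,2.8717392955053644,463.6810797636814,7.8493187592167395
rhizome-ME-r3,rhizome,ME,0.0,6.0,490.0,7.0
rhizome-ME-r3,rhizome,ME,365.0,2.864764877356039,464.80993531610886,7.868428331400773
rhizome-ME-r4,rhizome,ME,0.0,6.0,490.0,7.0
rhizome-ME-r4,rhizome,ME,365.0,2.888983991437572,460.91331114546085,7.802465223275091
root-HI-r1,root,HI,0.0,6.0,430.0,20.0
root-HI-r1,root,HI,365.0,2.428978501134202,389.289732048391,23.807982978779446
root-HI-r2,root,HI,0.0,6.0,430.0,20.0
root-HI-r2,root,HI,365.0,2.40423584434632,393.29602047212035,24.05299752385451
root-HI-r3,root,HI,0.0,6.0,430.0,20.0
root-HI-r3,root,HI,365.0,2.4054342271057014,393.10008114234944,24.041014366211197
root-HI-r4,root,HI,0.0,6.0,430.0,20.0
root-HI-r4,root,HI,365.0,2.4256342901228622,389.8264440390727,23.840806937098154
rhizome-HI-r1,rhizome,HI,0.0,6.0,490.0,7.0
rhizome-HI-r1,rhizome,HI,365.0,3.28672939992795,472.2563220472383,7.73613068665866
rhizome-HI-r2,rhizome,HI,0.0,6.0,490.0,7.0
rhizome-HI-r2,rhizome,HI,365.0,3.2653756030688874,475.3446239127043,7.786720812646866
rhizome-HI-r3,rhizome,HI,0.0,6.0,490.0,7.0
rhizome-HI-r3,rhizome,HI,365.0,3.3286822594808694,466.30426606610786,7.638628798860263
rhizome-HI-r4,rhizome,HI,0.0,6.0,490.0,7.0
rhizome-HI-r4,rhizome,HI,365.0,3.2933531064229604,471.30650368079796,7.720571511125513
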