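# Group-mean litter decomposition statistics from a one-year Phragmites
# australis belowground-litter bag incubation in a lacustrine wetland.
# treatment: L = rhizome litter, LR = root litter, M = 1:2 root:rhizome mix
# flooding: LO = non-flooded, ME = intermittently flooded, HI = permanently flooded
# mass_loss = fraction of initial dry mass lost after 365 days
# rate = two-time-point decomposition rate in formula units ((g/day) x 100)
# N, C in g/kg of remaining litter; CN_ratio as printed by the study
flooding,treatment,organ,mass_loss,rate,N_g_per_kg,C_g_per_kg,CN_ratio
LO,L,rhizome,0.3883,0.0035,6.7067,498.5767,74.3521
LO,LR,root,0.5049,0.0065,20.3000,418.5333,20.6171
LO,M,mixed,0.4344,0.0044,13.5450,453.5733,33.4895
ME,L,rhizome,0.5361,0.0066,7.1167,471.8433,66.2774
ME,LR,root,0.6488,0.0103,19.3433,450.0800,23.2703
ME,M,mixed,0.5850,0.0088,12.5367,405.2383,32.3377
HI,L,rhizome,0.4776,0.0060,8.5300,441.1567,51.7565
HI,LR,root,0.5450,0.0077,10.6800,167.6767,15.7091
HI,M,mixed,0.5156,0.0067,9.3067,294.6050,31.6617
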