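# Topology indices of soil bacterial and fungal co-occurrence networks
# after one year of belowground litter decomposition (field study).
# treatment: CK = no litter control, L = rhizome, LR = root, M = mixed.
community,treatment,nodes,edges,positive_pct,negative_pct,modularity,avg_clustering,avg_degree,avg_path_distance
bacteria,CK,391,7608,72.96,27.04,0.435,0.545,38.916,2.738
bacteria,L,427,12358,61.74,38.26,0.462,0.584,57.883,2.464
bacteria,LR,347,9487,54.74,45.26,0.277,0.582,54.68,2.697
bacteria,M,376,14883,51.19,48.81,0.296,0.648,79.165,2.266
fungi,CK,184,2636,86.49,13.51,0.448,0.708,28.652,2.841
fungi,L,211,2584,81.85,18.15,0.607,0.704,24.493,3.519
fungi,LR,195,2278,68.53,31.47,0.491,0.594,23.364,2.928
fungi,M,204,3310,92.48,7.52,0.542,0.735,32.451,2.787
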