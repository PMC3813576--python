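site,family,species,obs_minutes,L,H,CC,IPD
SB,Liliaceae,Allium roseum,50,11,1.50,0.87,79.72
SB,Liliaceae,Asphodelus fistulosus,135,12,1.94,0.92,0
SB,Scrophulariaceae,Bellardia trixago,71,4,0.93,0.78,0
SB,Gentianaceae,Blackstonia perfoliata,107,3,0.59,0.66,0
SB,Asteraceae,Centaurea aspera,120,17,1.66,0.88,46.42
SB,Gentianaceae,Centaurium erythraea,77,3,0.48,0.67,42.64
SB,Cistaceae,Cistus salviifolius,53,23,2.27,0.92,100
SB,Convulvulaceae,Convolvulus althaeoides,103,16,1.37,0.91,87.50
SB,Convulvulaceae,Convolvulus arvensis,113,25,1.63,0.95,87.03
SB,Asteraceae,Crepis vesicaria,67,15,2.14,0.92,97.74
SB,Apiaceae,Daucus carota,119,41,3.04,0.87,82.82
SB,Boraginaceae,Echium sabulicola,151,20,2.02,0.91,41.70
SB,Apiaceae,Foeniculum vulgare,42,10,1.78,0.78,61.31
SB,Asteraceae,Helichrysum stoechas,80,27,2.55,0.92,61.64
SB,Clusiaceae,Hypochoeris achyrophorus,68,11,2.02,0.86,96.43
SB,Asteraceae,Hypericum perforatum,80,9,1.66,0.80,19.74
SB,Fabaceae,Lotus corniculatus,147,18,2.38,0.89,100
SB,Fabaceae,Lotus cytisoides,89,9,1.43,0.88,100
SB,Fabaceae,Medicago litoralis,132,5,0.88,0.76,0
SB,Fabaceae,Melilotus indica,33,6,1.52,0.74,0
SB,Fabaceae,Melilotus segettalis,64,3,0.64,0.73,0
SB,Scrophulariaceae,Parentucellia viscosa,64,2,0.67,0.57,52.54
SB,Rosaceae,Potentilla reptans,86,28,2.62,0.96,98.96
SB,Asteraceae,Scabiosa maritima,120,24,1.87,0.95,78.45
SB,Caryophyllaceae,Silene vulgaris,70,3,0.36,0.77,96.77
SB,Lamiaceae,Teucrium dunense,92,28,2.08,0.94,63.84
SB,Scrophulariaceae,Verbascum sinuatum,101,11,1.49,0.78,85.02
PM,Caryophyllaceae,Arenaria grandiflora,75,8,1.75,0.73,77.02
PM,Asteraceae,Bellium bellidioides,135,13,2.20,0.86,75.81
PM,Asteraceae,Carlina corymbosa,80,18,1.86,0.82,96.72
PM,Asteraceae,Crepis triasii,85,14,2.12,0.89,94.68
PM,Rubiaceae,Galium balearicum,80,1,0,0.53,76.36
PM,Rubiaceae,Galium cinereum,85,2,0.28,0.70,25.61
PM,Cistaceae,Helianthemum apenninum,100,4,0.70,0.68,93.11
PM,Lamiaceae,Rosmarinus officinalis,45,9,1.39,0.79,42.40
PM,Asteraceae,Santolina chamaecyparissus,85,15,1.96,0.85,42.78
PM,Crassulaceae,Sedum dasyphyllum,90,8,1.84,0.82,89.90
PM,Lamiaceae,Teucrium asiaticum,135,13,1.93,0.74,65.25
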